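"""Independent brute-force oracles, implemented from first principles.

These deliberately avoid the code paths they check: quantiles by manual
order-statistic interpolation, the Cox partial likelihood by direct
summation over risk sets with a dense-grid maximizer, the Mann-Whitney
two-sided p by complete enumeration of group assignments, and
Benjamini-Hochberg by the step-up formula.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def quantile_linear(values, q):
    """Linear-interpolation quantile from sorted order statistics."""
    s = sorted(float(v) for v in values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def tukey_oracle(values, k=1.5):
    """(threshold, mask) by sort-interpolate-compare, strict inequality."""
    q25 = quantile_linear(values, 0.25)
    q75 = quantile_linear(values, 0.75)
    threshold = q75 + k * (q75 - q25)
    mask = [float(v) > threshold for v in values]
    return threshold, np.array(mask)


def switch_like_oracle(values):
    """Direct evaluation: median zero and 0 < nonzero fraction < 1/2."""
    values = [float(v) for v in values]
    s = sorted(values)
    n = len(s)
    median = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
    nonzero = sum(1 for v in values if v > 0)
    return median == 0 and 0 < nonzero / n < 0.5


def efron_loglik(beta, x, time, event):
    """Cox partial log-likelihood, Efron tie handling, direct summation."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        deaths = np.flatnonzero((time == t) & (event == 1))
        risk = np.flatnonzero(time >= t)
        d = deaths.size
        sr = np.exp(beta * x[risk]).sum()
        sd = np.exp(beta * x[deaths]).sum()
        ll += beta * x[deaths].sum()
        for l in range(d):
            ll -= math.log(sr - (l / d) * sd)
    return ll


def grid_maximize_efron(x, time, event, lo=-8.0, hi=8.0, n_coarse=4001, refine=3):
    """Dense-grid maximizer of the Efron partial likelihood, with refinement."""
    for _ in range(refine):
        grid = np.linspace(lo, hi, n_coarse)
        ll = np.array([efron_loglik(b, x, time, event) for b in grid])
        j = int(np.argmax(ll))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, grid.size - 1)]
    return float(grid[j])


def numeric_se_efron(beta_hat, x, time, event, h=1e-4):
    """Standard error from the numerical second derivative at the maximum."""
    d2 = (
        efron_loglik(beta_hat + h, x, time, event)
        - 2 * efron_loglik(beta_hat, x, time, event)
        + efron_loglik(beta_hat - h, x, time, event)
    ) / h**2
    return 1.0 / math.sqrt(-d2)


def mwu_exact_two_sided(x, y):
    """Two-sided Mann-Whitney p by complete enumeration (tie-free data).

    Enumerates every assignment of the pooled observations to the two
    groups; the p-value is the probability of a U at least as far into
    either tail as observed.
    """
    x, y = list(map(float, x)), list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for a in x for b in y if a > b)
    u_min = min(u_obs, n1 * n2 - u_obs)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in combo]
        u = sum(1 for a in g1 for b in pooled if b not in g1 and a > b)
        total += 1
        if u <= u_min or u >= n1 * n2 - u_min:
            extreme += 1
    return min(1.0, extreme / total)


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted values: min over j >= i of p_(j) * m / j."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def km_no_censoring(times):
    """Closed-form Kaplan-Meier for all-event data: S drops by 1/n per event."""
    times = sorted(map(float, times))
    n = len(times)
    out = {}
    remaining = n
    for t in times:
        remaining -= 1
        out[t] = remaining / n
    return out
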