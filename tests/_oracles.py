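"""Independent brute-force oracles used to cross-check the fitters.

These deliberately avoid the package's Levenberg-style nonlinear least
squares: both exponential and Michaelis–Menten models are linear in part of
their parameters, so the oracles profile the nonlinear parameter over a
coarse grid and polish it with a 1-D bounded scalar minimizer, solving the
linear part exactly at each step.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar


def grid_fit_single_exponential(times, signals, n_grid: int = 200):
    """Profile-likelihood fit of A(1-exp(-k t)) + B.

    For fixed k the model is linear in (A, B); SSE(k) is minimized over a
    log-spaced grid spanning the observable rate range, then polished with a
    bounded 1-D minimizer.  Returns (A, k, B, sse).
    """
    t = np.asarray(times, float)
    s = np.asarray(signals, float)
    span = t[-1] - t[0]

    def sse_of(logk):
        k = math.exp(logk)
        x = -np.expm1(-k * t)
        design = np.column_stack([x, np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(design, s, rcond=None)
        resid = design @ coef - s
        return float(resid @ resid), coef

    lo, hi = math.log(1e-3 / span), math.log(1e3 / (t[1] - t[0]))
    grid = np.linspace(lo, hi, n_grid)
    sses = [sse_of(g)[0] for g in grid]
    i = int(np.argmin(sses))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda g: sse_of(g)[0], bounds=(a, b),
                          method="bounded",
                          options={"xatol": 1e-12})
    sse, coef = sse_of(res.x)
    return float(coef[0]), math.exp(res.x), float(coef[1]), sse


def grid_fit_michaelis_menten(concs, rates, n_grid: int = 400):
    """Profile fit of v = Vmax·S/(Km+S): Vmax solved in closed form for each
    Km on a log grid, Km polished by a bounded 1-D minimizer.
    Returns (Vmax, Km, sse)."""
    s = np.asarray(concs, float)
    v = np.asarray(rates, float)
    pos = s[s > 0]

    def sse_of(logkm):
        km = math.exp(logkm)
        x = s / (km + s)
        vmax = float(np.sum(v * x) / np.sum(x * x))
        resid = vmax * x - v
        return float(resid @ resid), vmax

    lo, hi = math.log(pos.min() / 100.0), math.log(pos.max() * 100.0)
    grid = np.linspace(lo, hi, n_grid)
    sses = [sse_of(g)[0] for g in grid]
    i = int(np.argmin(sses))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda g: sse_of(g)[0], bounds=(a, b),
                          method="bounded", options={"xatol": 1e-12})
    sse, vmax = sse_of(res.x)
    return vmax, math.exp(res.x), sse


def ols_closed_form(x, y):
    """Normal-equations OLS: returns (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    return slope, (sy - slope * sx) / n


def runs_pvalue_enumeration(signs) -> float:
    """Exact one-sided runs-test p by exhaustive enumeration of all
    arrangements of the observed numbers of + and − signs (tiny n only)."""
    signs = [1 if s > 0 else -1 for s in signs if s != 0]
    n_pos = signs.count(1)

    def runs_of(seq):
        return 1 + sum(a != b for a, b in zip(seq, seq[1:]))

    r_obs = runs_of(signs)
    n = len(signs)
    total = 0
    at_most = 0
    for positions in itertools.combinations(range(n), n_pos):
        seq = [-1] * n
        for p in positions:
            seq[p] = 1
        total += 1
        if runs_of(seq) <= r_obs:
            at_most += 1
    return at_most / total
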