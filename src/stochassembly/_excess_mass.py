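"""Excess-mass and dip statistics for multimodality assessment.

The excess-mass functional E_{n,m}(lam) is the largest total "excess"
(empirical mass minus lam times interval length) attainable by m disjoint
closed intervals.  The test statistic for a null of k modes is

    D_{n,k} = max_lam [ E_{n,k+1}(lam) - E_{n,k}(lam) ],

evaluated exactly over intervals whose endpoints are order statistics and
over the finite grid of candidate slopes lam = (j-i) / (n (x_(j) - x_(i))).
For k = 1 the statistic equals twice Hartigan's dip statistic, which is
also implemented independently below and used as a cross-check.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


def lambda_candidates(x: np.ndarray) -> np.ndarray:
    """Candidate penalty slopes: empirical densities over all order-statistic pairs."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    ok = dx > 0
    lam = (j[ok] - i[ok]) / (n * dx[ok])
    return np.unique(np.concatenate([[0.0], lam]))


@njit(cache=False)
def _em_kernel(x, lam, kmax):  # pragma: no cover - compiled
    n = x.size
    L = lam.size
    E = np.zeros((kmax, L))
    for li in range(L):
        lv = lam[li]
        g_prev = np.zeros(n)
        for m in range(kmax):
            w = -1e300
            best = -1e300
            g_new = np.empty(n)
            prev_g = 0.0  # g_{m-1}(j-1), with g_{m-1}(-1) = 0
            for j in range(n):
                v = j / n - lv * x[j]
                cw = prev_g - v
                if cw > w:
                    w = cw
                c = (j + 1) / n - lv * x[j] + w
                if c > best:
                    best = c
                if g_prev[j] > best:
                    best = g_prev[j]
                g_new[j] = best
                prev_g = g_prev[j]
            g_prev = g_new
            E[m, li] = g_prev[n - 1]
    return E


def _em_numpy(x, lam, kmax):
    n = x.size
    u = (np.arange(1, n + 1) / n)[None, :] - lam[:, None] * x[None, :]
    v = (np.arange(0, n) / n)[None, :] - lam[:, None] * x[None, :]
    E = np.empty((kmax, lam.size))
    g_prev = np.zeros((lam.size, n))
    for m in range(kmax):
        gshift = np.concatenate([np.zeros((lam.size, 1)), g_prev[:, :-1]], axis=1)
        w = np.maximum.accumulate(gshift - v, axis=1)
        g = np.maximum.accumulate(u + w, axis=1)
        g = np.maximum(g, g_prev)
        E[m] = g[:, -1]
        g_prev = g
    return E


def excess_mass_profile(x: np.ndarray, lam: np.ndarray, kmax: int) -> np.ndarray:
    """E_{n,m}(lam) for m = 1..kmax; shape (kmax, len(lam))."""
    x = np.sort(np.asarray(x, dtype=float))
    lam = np.ascontiguousarray(np.atleast_1d(lam), dtype=float)
    if _HAVE_NUMBA:
        return _em_kernel(x, lam, kmax)
    return _em_numpy(x, lam, kmax)


#: Above this many candidate slopes the grid is thinned to an evenly spaced
#: subsample (the profile is piecewise linear and flat near its maximum, so
#: thinning changes the statistic negligibly for large n).
MAX_LAMBDA = 8000


def excess_mass_statistic(values: np.ndarray, null_modes: int = 1) -> float:
    """Excess-mass multimodality statistic against a null of ``null_modes`` modes.

    Requires at least 5 observations.  Degenerate (constant) samples give 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 5:
        raise ValueError("excess-mass statistic requires n >= 5")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        return 0.0
    lam = lambda_candidates(x)
    if lam.size > MAX_LAMBDA:
        keep = np.unique(np.linspace(0, lam.size - 1, MAX_LAMBDA).astype(int))
        lam = lam[keep]
    E = excess_mass_profile(x, lam, null_modes + 1)
    return float(np.max(E[null_modes] - E[null_modes - 1]))


def _convex_minorant_indices(y: np.ndarray, x: np.ndarray) -> list:
    """Touch points of the greatest convex minorant through (x_i, y_i)."""
    idx = [0]
    for i in range(1, len(x)):
        idx.append(i)
        while len(idx) >= 3:
            a, b, c = idx[-3], idx[-2], idx[-1]
            if (y[b] - y[a]) * (x[c] - x[a]) >= (y[c] - y[a]) * (x[b] - x[a]):
                idx.pop(-2)
            else:
                break
    return idx


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan & Hartigan's dip: sup-distance from the ECDF to the closest
    unimodal CDF, located via alternating convex-minorant / concave-majorant
    refinement of the modal interval."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    low, high = 0, n - 1
    d = 0.0
    while True:
        xs = x[low:high + 1]
        lo_vals = np.arange(low, high + 1) / n
        hi_vals = (np.arange(low, high + 1) + 1) / n
        gcm = [low + i for i in _convex_minorant_indices(lo_vals, xs)]
        lcm_rev = _convex_minorant_indices(-hi_vals[::-1], -xs[::-1])
        lcm = sorted(high - i for i in lcm_rev)

        def on_curve(idxs, vals, t):
            xs_ = np.array([x[i] for i in idxs])
            ys_ = np.array([vals(i) for i in idxs])
            return float(np.interp(x[t], xs_, ys_))

        upper = lambda i: (i + 1) / n  # noqa: E731
        lower = lambda i: i / n  # noqa: E731
        d_g = max(on_curve(lcm, upper, t) - t / n for t in gcm)
        d_l = max((t + 1) / n - on_curve(gcm, lower, t) for t in lcm)
        if max(d_g, d_l) <= d:
            return d / 2.0
        if d_g >= d_l:
            ig = max(gcm, key=lambda t: on_curve(lcm, upper, t) - t / n)
            right = [t for t in lcm if x[t] >= x[ig]]
            ih = min(right) if right else high
        else:
            ih = max(lcm, key=lambda t: (t + 1) / n - on_curve(gcm, lower, t))
            left = [t for t in gcm if x[t] <= x[ih]]
            ig = max(left) if left else low
        dl = max(((t + 1) / n - on_curve(gcm, lower, t) for t in range(low, ig + 1)),
                 default=0.0)
        dr = max((on_curve(lcm, upper, t) - t / n for t in range(ih, high + 1)),
                 default=0.0)
        d = max(d, dl, dr)
        if ig == low and ih == high:
            return d / 2.0
        low, high = ig, ih
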