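"""OTU-level multimodality and within-mode variation.

Among-replicate variation of a taxon's abundance is summarized by two
indices that map onto a ball-and-cup picture of community assembly:

* a multimodality index (the excess-mass statistic, optionally Hartigan's
  dip) detecting splits of replicates into alternative abundance modes
  ("basins"), with a p-value from a calibrated smoothed bootstrap, and
* within-mode variation: the standard deviation sigma of additive
  Gaussian noise in a Binomial(depth, p) + round(Normal(0, sigma))
  convolution mixture fitted to the replicate counts inside one mode.

Both indices can then be regressed against the founding coefficient of
variation to ask whether initial demographic stochasticity propagates into
among-replicate divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ._excess_mass import dip_statistic, excess_mass_statistic

__all__ = [
    "ModalityResult",
    "MixtureFit",
    "WithinModeVariation",
    "clr_transform",
    "excess_mass_statistic",
    "dip_statistic",
    "multimodality_test",
    "fit_binomial_normal",
    "within_mode_variation",
    "scale_statistics",
    "regress_vs_cv",
]


@dataclass
class ModalityResult:
    """Outcome of a multimodality test on one vector of values."""

    statistic: float
    p_value: float
    n_modes: int
    mode_assignments: np.ndarray
    method: str = "excess_mass"
    scaled_statistic: float | None = None
    p_by_modes: dict = field(default_factory=dict)
    low_bootstrap: bool = False


@dataclass
class MixtureFit:
    """MLE of the binomial + discretized-normal convolution mixture."""

    p_hat: float
    sigma_hat: float
    loglik: float
    n_in_mode: int


@dataclass
class WithinModeVariation:
    value: float
    per_mode: dict
    excluded_modes: list
    reason: str | None = None


def clr_transform(counts, pseudocount: float = 0.5):
    """Centered log-ratio transform, one composition per row.

    Each row becomes ln(x + pc) minus its mean, so rows sum to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = np.asarray(counts, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] == 0:
        raise ValueError("empty sample")
    logx = np.log(x + pseudocount)
    out = logx - logx.mean(axis=1, keepdims=True)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out if np.asarray(counts).ndim > 1 else out[0]


def _kde_density(x, h, grid):
    z = (grid[:, None] - x[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))


def _n_kde_modes(x, h, grid):
    d = _kde_density(x, h, grid)
    return int(np.sum((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])))


def _critical_bandwidth(x, k, grid, tol=1e-3):
    """Smallest KDE bandwidth at which the density has at most k modes."""
    s = x.std()
    lo, hi = 1e-6 * s, 4.0 * s
    while _n_kde_modes(x, hi, grid) > k:  # pragma: no cover - defensive
        hi *= 2
    while hi / lo > 1 + tol:
        mid = np.sqrt(lo * hi)
        if _n_kde_modes(x, mid, grid) <= k:
            hi = mid
        else:
            lo = mid
    return hi


def _make_grid(x, pad=0.15, size=512):
    lo, hi = x.min(), x.max()
    span = (hi - lo) or 1.0
    return np.linspace(lo - pad * span, hi + pad * span, size)


def multimodality_test(
    values,
    B: int = 500,
    seed=None,
    alpha: float = 0.05,
    method: str = "excess_mass",
    max_modes: int = 3,
) -> ModalityResult:
    """Calibrated multimodality test on a vector of values.

    For each candidate null k = 1, 2, ... the statistic is compared against
    its distribution under B smoothed-bootstrap resamples drawn from the
    critical-bandwidth KDE (the closest k-modal smoothed version of the data,
    variance-rescaled).  ``n_modes`` is the smallest k not rejected at
    ``alpha``; the reported p-value is for the unimodal null.  Replicates are
    then assigned to modes by cutting at the antimodes of the k-modal KDE.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 5:
        raise ValueError("multimodality test requires n >= 5")
    low_bootstrap = B < 100
    if low_bootstrap:
        warnings.warn("bootstrap replicate count below 100; p-values are coarse")
    if method not in ("excess_mass", "dip"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)

    if np.ptp(x) == 0:
        return ModalityResult(0.0, 1.0, 1, np.zeros(x.size, dtype=int), method,
                              p_by_modes={1: 1.0}, low_bootstrap=low_bootstrap)

    def stat(v, k):
        if method == "dip" and k == 1:
            return 2.0 * dip_statistic(v)
        return excess_mass_statistic(v, k)

    grid = _make_grid(x)
    mean, var = x.mean(), x.var()
    p_by_modes = {}
    n_modes = max_modes
    h_by_modes = {}
    for k in range(1, max_modes + 1):
        obs = stat(x, k)
        h = _critical_bandwidth(x, k, grid)
        h_by_modes[k] = h
        shrink = 1.0 / np.sqrt(1.0 + h * h / var) if var > 0 else 1.0
        exceed = 0
        for _ in range(B):
            idx = rng.integers(0, x.size, x.size)
            y = mean + (x[idx] - mean + h * rng.standard_normal(x.size)) * shrink
            if stat(y, k) >= obs:
                exceed += 1
        p_by_modes[k] = (1 + exceed) / (B + 1)
        if p_by_modes[k] > alpha:
            n_modes = k
            break

    statistic = stat(x, 1)
    p_value = p_by_modes[1]
    if n_modes == 1:
        assignments = np.zeros(x.size, dtype=int)
    else:
        # bandwidth floor: the antimode search needs the KDE resolved on the
        # evaluation grid even when the critical bandwidth is tiny
        h = max(h_by_modes[n_modes] * (1 + 1e-6), 2.5 * (grid[1] - grid[0]))
        dens = _kde_density(x, h, grid)
        is_min = (dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])
        antimodes = grid[1:-1][is_min]
        # keep the n_modes - 1 deepest antimodes
        if antimodes.size > n_modes - 1:
            order = np.argsort(dens[1:-1][is_min])
            antimodes = np.sort(antimodes[order[: n_modes - 1]])
        assignments = np.searchsorted(antimodes, x, side="left")
    return ModalityResult(statistic, p_value, n_modes, assignments, method,
                          p_by_modes=p_by_modes, low_bootstrap=low_bootstrap)


def _discrete_normal_kernel(sigma: float):
    """P(round(N(0, sigma)) = d) on d in [-D, D], D = ceil(6 sigma)."""
    if sigma < 1e-8:
        return np.array([0]), np.array([1.0])
    D = max(1, int(np.ceil(6 * sigma)))
    d = np.arange(-D, D + 1)
    q = stats.norm.cdf((d + 0.5) / sigma) - stats.norm.cdf((d - 0.5) / sigma)
    return d, q / q.sum()


def _bn_negloglik(p, sigma, counts, depths):
    d, q = _discrete_normal_kernel(sigma)
    z = counts[:, None] - d[None, :]
    pm = stats.binom.pmf(z, depths[:, None], p)
    lik = pm @ q
    return -np.sum(np.log(np.maximum(lik, 1e-300)))


def fit_binomial_normal(counts, depths) -> MixtureFit:
    """MLE of (p, sigma) for count = Binomial(depth, p) + round(Normal(0, sigma)).

    The likelihood is the discrete convolution of the binomial pmf with a
    CDF-discretized Gaussian kernel truncated at +/- 6 sigma; sigma is in
    count units.
    """
    counts = np.asarray(counts, dtype=float).ravel()
    depths = np.asarray(depths, dtype=float).ravel()
    if counts.size != depths.size:
        raise ValueError("counts and depths length mismatch")
    if counts.size < 3:
        raise ValueError("insufficient replicates (need >= 3)")
    if np.any(counts > depths):
        raise ValueError("counts exceed depths")
    if np.any(counts < 0) or np.any(depths < 1):
        raise ValueError("counts must be nonnegative and depths >= 1")

    p0 = np.clip(np.mean(counts / depths), 1e-6, 1 - 1e-6)
    binom_var = np.mean(depths * p0 * (1 - p0))
    s0 = np.sqrt(max(0.0, np.var(counts) - binom_var))
    smax = 3.0 * counts.std() + 10.0

    def nll(theta):
        p = 1.0 / (1.0 + np.exp(-theta[0]))
        return _bn_negloglik(p, theta[1], counts, depths)

    best = None
    for s_start in {s0, 0.5 * smax}:
        res = optimize.minimize(
            nll,
            x0=[np.log(p0 / (1 - p0)), s_start],
            method="Nelder-Mead",
            bounds=[(-20, 20), (0.0, smax)],
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    p_hat = 1.0 / (1.0 + np.exp(-best.x[0]))
    return MixtureFit(float(p_hat), float(best.x[1]), float(-best.fun), counts.size)


def within_mode_variation(counts, depths, modality: ModalityResult,
                          min_mode_size: int = 3) -> WithinModeVariation:
    """Average within-mode sigma over the modes of a modality result.

    Modes with fewer than ``min_mode_size`` replicates are excluded; if no
    mode is large enough the value is NaN with a reason.
    """
    counts = np.asarray(counts, dtype=float).ravel()
    depths = np.asarray(depths, dtype=float).ravel()
    labels = np.asarray(modality.mode_assignments)
    per_mode, excluded = {}, []
    for lab in np.unique(labels):
        mask = labels == lab
        if mask.sum() < min_mode_size:
            excluded.append(int(lab))
            continue
        per_mode[int(lab)] = fit_binomial_normal(counts[mask], depths[mask]).sigma_hat
    if not per_mode:
        return WithinModeVariation(float("nan"), {}, excluded,
                                   reason="all modes below minimum size")
    return WithinModeVariation(float(np.mean(list(per_mode.values()))),
                               per_mode, excluded)


def scale_statistics(statistics) -> np.ndarray:
    """Min-max scale a panel of statistics to [0, 1] (constant panel -> zeros)."""
    s = np.asarray(statistics, dtype=float)
    span = np.nanmax(s) - np.nanmin(s)
    if span == 0 or not np.isfinite(span):
        return np.zeros_like(s)
    return (s - np.nanmin(s)) / span


def regress_vs_cv(metric, cv, groups=None, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per-group OLS of a divergence metric on founding CV, BH-corrected.

    Groups with a constant predictor (or < 3 usable points) are flagged and
    excluded from the correction.  Returns one row per group with slope,
    intercept, p-value, BH q-value and a significance flag at ``fdr_alpha``.
    """
    df = pd.DataFrame({"metric": np.asarray(metric, float),
                       "cv": np.asarray(cv, float)})
    df["group"] = "all" if groups is None else list(groups)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        sub = sub.dropna()
        if len(sub) < 3 or np.ptp(sub["cv"].to_numpy()) == 0:
            rows.append({"group": g, "n": len(sub), "slope": np.nan,
                         "intercept": np.nan, "p_value": np.nan,
                         "flag": "constant_or_small"})
            continue
        res = stats.linregress(sub["cv"], sub["metric"])
        rows.append({"group": g, "n": len(sub), "slope": res.slope,
                     "intercept": res.intercept, "p_value": res.pvalue,
                     "flag": ""})
    out = pd.DataFrame(rows).set_index("group")
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = multipletests(out.loc[ok, "p_value"],
                                               method="fdr_bh")[1]
    out["significant"] = out["q_value"] < fdr_alpha
    return out
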