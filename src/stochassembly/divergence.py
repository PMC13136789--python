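"""Community-scale differentiation among replicate communities.

Replicate divergence is read off the distribution of pairwise
beta-diversity values: a multimodal dissimilarity histogram indicates that
replicates split into alternative compositional clusters (basins), while
the spread inside one cluster beyond pure multinomial resampling noise
measures within-mode variation.  The within-mode estimator matches
variances: observed within-cluster dissimilarity variance minus the
variance of a multinomial-resampling baseline around the cluster mean
profile, the surplus being attributed to additive normal broadening of
width sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .modality import ModalityResult, excess_mass_statistic, multimodality_test

__all__ = [
    "DissimilarityDistribution",
    "CommunityWithinMode",
    "pairwise_dissimilarity",
    "community_multimodality",
    "community_within_mode_variation",
]

METRICS = ("bray_curtis", "jaccard", "jensen_shannon", "hellinger")


@dataclass
class DissimilarityDistribution:
    metric_name: str
    values: np.ndarray          # condensed upper triangle, m(m-1)/2
    matrix: np.ndarray          # full symmetric form, zero diagonal
    replicate_ids: list


def _as_matrix(counts):
    if isinstance(counts, pd.DataFrame):
        ids = list(counts.index)
        x = counts.to_numpy(dtype=float)
    else:
        x = np.asarray(counts, dtype=float)
        ids = list(range(x.shape[0]))
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a matrix with >= 2 replicate rows")
    zero = np.where(x.sum(axis=1) == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample {ids[zero[0]]!r}")
    return x, ids


def pairwise_dissimilarity(counts, metric: str = "bray_curtis"
                           ) -> DissimilarityDistribution:
    """All pairwise dissimilarities between replicate rows of a count matrix.

    Bray-Curtis acts on raw counts, Jaccard on presence/absence,
    Jensen-Shannon distance (natural log, rescaled by 1/sqrt(ln 2) onto
    [0, 1]) and Hellinger on relative abundances.
    """
    x, ids = _as_matrix(counts)
    if metric == "bray_curtis":
        vals = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        vals = pdist(x > 0, metric="jaccard")
    elif metric == "jensen_shannon":
        rel = x / x.sum(axis=1, keepdims=True)
        vals = pdist(rel, metric="jensenshannon") / np.sqrt(np.log(2))
    elif metric == "hellinger":
        rel = x / x.sum(axis=1, keepdims=True)
        vals = pdist(np.sqrt(rel), metric="euclidean") / np.sqrt(2)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    vals = np.clip(vals, 0.0, 1.0)
    return DissimilarityDistribution(metric, vals, squareform(vals), ids)


def community_multimodality(dist: DissimilarityDistribution, B: int = 500,
                            seed=None, alpha: float = 0.05,
                            counts=None) -> ModalityResult:
    """Multimodality of a pairwise-dissimilarity distribution.

    The excess-mass statistic is computed on the m(m-1)/2 dissimilarity
    values.  Because pairs sharing a replicate are dependent, the null
    distribution is built at the replicate level: B pseudo-datasets are
    drawn by multinomial resampling of each replicate's reads from the
    pooled mean relative-abundance profile (the closest single-cluster
    model), and the pairwise statistic is recomputed on each.  ``counts``
    (replicates x taxa) enables this replicate-level calibration; without
    it a value-level smoothed bootstrap is used as fallback.  Replicates
    are assigned to modes by cutting an average-linkage tree at the
    detected mode count.
    """
    m = len(dist.replicate_ids)
    if m < 5:
        raise ValueError("community multimodality requires >= 5 replicates")
    rng = np.random.default_rng(seed)
    obs = excess_mass_statistic(dist.values, 1)

    if counts is not None:
        x, _ = _as_matrix(counts)
        depths = x.sum(axis=1).astype(int)
        pooled = x.sum(axis=0)
        pooled = pooled / pooled.sum()
        exceed = 0
        for _ in range(B):
            sim = np.vstack([rng.multinomial(d, pooled) for d in depths])
            null_vals = pairwise_dissimilarity(sim, dist.metric_name).values
            if excess_mass_statistic(null_vals, 1) >= obs:
                exceed += 1
        p_value = (1 + exceed) / (B + 1)
        if p_value > alpha:
            n_modes = 1
        else:
            # mode count beyond rejection from the value-level calibrated test
            inner = multimodality_test(dist.values, B=min(B, 100), seed=rng,
                                       alpha=alpha)
            n_modes = max(2, inner.n_modes)
        result = ModalityResult(obs, p_value, n_modes,
                                np.zeros(m, dtype=int), "excess_mass",
                                p_by_modes={1: p_value})
    else:
        result = multimodality_test(dist.values, B=B, seed=rng, alpha=alpha)
        n_modes = result.n_modes

    if n_modes > 1:
        tree = linkage(dist.values, method="average")
        labels = fcluster(tree, t=n_modes, criterion="maxclust") - 1
    else:
        labels = np.zeros(m, dtype=int)
    result.mode_assignments = labels
    result.n_modes = n_modes
    return result


@dataclass
class CommunityWithinMode:
    mean_sigma: float
    per_cluster: dict
    excluded_clusters: list
    baseline_var: dict
    observed_var: dict


def community_within_mode_variation(counts, cluster_labels, n_sim: int = 96,
                                    seed=None, metric: str = "bray_curtis",
                                    min_cluster_size: int = 3
                                    ) -> CommunityWithinMode:
    """Within-cluster variation beyond multinomial sampling noise.

    Per cluster, a baseline dissimilarity distribution is simulated by
    ``n_sim`` multinomial read draws from the cluster mean relative-abundance
    profile at the observed depths; sigma^2 is the excess of the observed
    within-cluster dissimilarity variance over that baseline (floored at 0).
    """
    x, _ = _as_matrix(counts)
    labels = np.asarray(cluster_labels)
    rng = np.random.default_rng(seed)
    per, base_v, obs_v, excluded = {}, {}, {}, []
    for lab in np.unique(labels):
        mask = labels == lab
        if mask.sum() < min_cluster_size:
            excluded.append(int(lab))
            warnings.warn(f"cluster {lab} below {min_cluster_size} replicates; skipped")
            continue
        sub = x[mask]
        depths = sub.sum(axis=1).astype(int)
        mean_rel = sub.sum(axis=0) / sub.sum()
        obs_vals = pairwise_dissimilarity(sub, metric).values
        sim_depths = depths[np.arange(n_sim) % depths.size]
        sim = np.vstack([rng.multinomial(d, mean_rel) for d in sim_depths])
        base_vals = pairwise_dissimilarity(sim, metric).values
        v_obs = float(np.var(obs_vals))
        v_base = float(np.var(base_vals))
        per[int(lab)] = float(np.sqrt(max(0.0, v_obs - v_base)))
        base_v[int(lab)], obs_v[int(lab)] = v_base, v_obs
    mean_sigma = float(np.mean(list(per.values()))) if per else float("nan")
    return CommunityWithinMode(mean_sigma, per, excluded, base_v, obs_v)
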