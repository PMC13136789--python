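"""Ecological dynamic-regime analysis of replicate trajectories.

Each replicate's time series of community states (typically mMDS
coordinates) forms a directed trajectory.  Trajectory-to-trajectory
distance is a directed segment path dissimilarity: every segment of one
trajectory is matched to the closest direction-respecting position on the
other, and the two directed means are averaged.  A regime of m trajectories
is then summarized by

* dDis — mean dissimilarity of all trajectories to a representative
  trajectory (the reference's zero self-distance is included, matching the
  1/m normalization),
* dBD — mean dissimilarity over unordered trajectory pairs,
* dEve — a minimum-spanning-tree evenness of trajectory spacing (the
  functional-evenness form), 1 when trajectories are evenly spread and
  low when they clump into subclusters.

With point distances normalized to [0, 1], all three metrics live in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.stats import gaussian_kde

__all__ = [
    "Trajectory",
    "RegimeMetrics",
    "segment_path_dissimilarity",
    "trajectory_dissimilarity_matrix",
    "representative_trajectory",
    "dynamic_dispersion",
    "dynamic_beta_diversity",
    "dynamic_evenness",
    "regime_report",
]

CRITERIA = ("average_depth", "medoid", "density", "size", "length")


@dataclass
class Trajectory:
    replicate_id: str
    times: np.ndarray
    points: np.ndarray  # (T, dim)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] != self.times.size:
            raise ValueError("times and points length mismatch")
        if self.times.size < 2:
            raise ValueError("trajectory needs >= 2 states")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time labels must be strictly increasing")

    @property
    def segments(self):
        return [(self.points[i], self.points[i + 1])
                for i in range(self.points.shape[0] - 1)]

    @property
    def path_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def _point_to_segment(p, a, b):
    """(distance, parameter t in [0,1]) of closest point on segment ab to p."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab))), t


def _segment_to_segment(p0, p1, a, b):
    """Directed distance from segment (p0 -> p1) to segment (a -> b).

    Matches p0 and p1 to positions t0 <= t1 along ab (direction respected),
    minimizing the mean endpoint distance.  If the unconstrained projections
    already respect the order they are optimal; otherwise the optimum has
    t0 = t1 and a 1-D convex minimization locates it.
    """
    d0, t0 = _point_to_segment(p0, a, b)
    d1, t1 = _point_to_segment(p1, a, b)
    if t0 <= t1:
        return 0.5 * (d0 + d1)
    ab = b - a

    def cost(t):
        q = a + t * ab
        return 0.5 * (np.linalg.norm(p0 - q) + np.linalg.norm(p1 - q))

    res = minimize_scalar(cost, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.fun)


def _segment_to_trajectory(p0, p1, segments):
    """Directed distance from segment (p0 -> p1) to a whole trajectory.

    The endpoints may match different segments as long as p1's match does
    not precede p0's along the trajectory ordering; within one segment the
    ordered matching of ``_segment_to_segment`` applies.
    """
    d0 = np.empty(len(segments))
    d1 = np.empty(len(segments))
    for k, (a, b) in enumerate(segments):
        d0[k], _ = _point_to_segment(p0, a, b)
        d1[k], _ = _point_to_segment(p1, a, b)
    best = min(_segment_to_segment(p0, p1, a, b) for a, b in segments)
    prefix = np.minimum.accumulate(d0)
    for j in range(1, len(segments)):
        best = min(best, 0.5 * (prefix[j - 1] + d1[j]))
    return float(best)


def segment_path_dissimilarity(traj_i: Trajectory, traj_j: Trajectory) -> float:
    """Symmetrized directed segment path dissimilarity between two trajectories."""

    def directed(a, b):
        segs = b.segments
        return float(np.mean([_segment_to_trajectory(p0, p1, segs)
                              for p0, p1 in a.segments]))

    return 0.5 * (directed(traj_i, traj_j) + directed(traj_j, traj_i))


def trajectory_dissimilarity_matrix(trajectories) -> np.ndarray:
    m = len(trajectories)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = segment_path_dissimilarity(trajectories[i],
                                                           trajectories[j])
    return D


def representative_trajectory(trajectories, criterion: str = "average_depth",
                              dmat=None) -> Trajectory:
    """Pick the input trajectory that best summarizes the regime.

    average_depth / density: highest mean / total kernel density of its
    states (Gaussian KDE over all states of all trajectories); medoid:
    smallest summed dissimilarity to the others; size: most observed states;
    length: greatest path length.  Ties fall back to the medoid ordering.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("empty trajectory set")
    if len(trajectories) == 1:
        return trajectories[0]
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if dmat is None and criterion in ("medoid", "size", "length"):
        dmat = trajectory_dissimilarity_matrix(trajectories)
    medoid_rank = (np.argsort(dmat.sum(axis=1)) if dmat is not None
                   else np.arange(len(trajectories)))

    if criterion == "medoid":
        return trajectories[int(np.argmin(dmat.sum(axis=1)))]
    if criterion in ("average_depth", "density"):
        pts = np.vstack([t.points for t in trajectories])
        try:
            kde = gaussian_kde(pts.T)
            dens = [kde(t.points.T) for t in trajectories]
        except np.linalg.LinAlgError:  # degenerate cloud: fall back to medoid
            return representative_trajectory(trajectories, "medoid", dmat)
        score = [d.mean() if criterion == "average_depth" else d.sum()
                 for d in dens]
        return trajectories[int(np.argmax(score))]
    key = ((lambda t: t.times.size) if criterion == "size"
           else (lambda t: t.path_length))
    vals = np.array([key(t) for t in trajectories])
    best = np.where(vals == vals.max())[0]
    if best.size == 1:
        return trajectories[int(best[0])]
    for idx in medoid_rank:  # tie-break toward the medoid
        if idx in best:
            return trajectories[int(idx)]
    raise AssertionError  # pragma: no cover


def dynamic_dispersion(trajectories, reference: Trajectory, dmat=None) -> float:
    """dDis: mean dissimilarity of the m trajectories to the reference
    (the reference's own zero distance counts toward the mean)."""
    trajectories = list(trajectories)
    ref_idx = next((i for i, t in enumerate(trajectories) if t is reference), None)
    if dmat is not None and ref_idx is not None:
        return float(dmat[ref_idx].sum() / len(trajectories))
    d = [0.0 if t is reference else segment_path_dissimilarity(t, reference)
         for t in trajectories]
    return float(np.mean(d))


def dynamic_beta_diversity(trajectories, dmat=None) -> float:
    """dBD: mean directed segment path dissimilarity over unordered pairs."""
    m = len(trajectories)
    if m < 2:
        raise ValueError("dBD needs >= 2 trajectories")
    if dmat is None:
        dmat = trajectory_dissimilarity_matrix(trajectories)
    iu = np.triu_indices(m, k=1)
    return float(dmat[iu].mean())


def dynamic_evenness(trajectories=None, dmat=None) -> float:
    """dEve: MST-based evenness of trajectory spacing (functional-evenness form).

    With EW_c = weight of MST edge c over the summed weights,
    dEve = [sum_c min(EW_c, 1/(m-1)) - 1/(m-1)] / [1 - 1/(m-1)].
    """
    if dmat is None:
        dmat = trajectory_dissimilarity_matrix(list(trajectories))
    m = dmat.shape[0]
    if m < 3:
        raise ValueError("dEve needs >= 3 trajectories")
    mst = minimum_spanning_tree(dmat).toarray()
    w = mst[mst > 0]
    if w.size < m - 1:  # zero-weight edges were dropped by sparsity
        if np.allclose(dmat, 0):
            warnings.warn("all trajectory dissimilarities are zero; dEve = 1")
            return 1.0
        w = np.concatenate([w, np.zeros(m - 1 - w.size)])
    ew = w / w.sum()
    thr = 1.0 / (m - 1)
    return float((np.minimum(ew, thr).sum() - thr) / (1.0 - thr))


@dataclass
class RegimeMetrics:
    setting: tuple
    dDis: float
    dBD: float
    dEve: float
    m: int
    reference_id: str
    criterion: str


def build_trajectories(table, coords: pd.DataFrame) -> dict:
    """Per-replicate trajectories through an embedded state space.

    ``coords``: DataFrame of embedding coordinates indexed by sample ID.
    Returns {(source, dilution, replicate): Trajectory}; replicates with a
    single time point are dropped with a warning.
    """
    out = {}
    for key, sub in table.meta.groupby(["source", "dilution", "replicate"],
                                       sort=True):
        sub = sub.sort_values("day")
        if len(sub) < 2:
            warnings.warn(f"replicate {key} has < 2 time points; dropped")
            continue
        out[key] = Trajectory("_".join(map(str, key)),
                              sub["day"].to_numpy(),
                              coords.loc[sub.index].to_numpy())
    return out


def regime_report(table, coords: pd.DataFrame, per_dilution: bool = True,
                  criterion: str = "average_depth") -> pd.DataFrame:
    """dDis / dBD / dEve per inoculum setting.

    Coordinates are globally rescaled so the largest pairwise state distance
    is 1, keeping all metrics in [0, 1].  Settings with fewer than 3 usable
    trajectories are skipped with a warning.
    """
    pts = coords.to_numpy(dtype=float)
    span = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).max()
    coords = coords / span if span > 0 else coords
    trajs = build_trajectories(table, coords)
    keys = pd.DataFrame([k for k in trajs],
                        columns=["source", "dilution", "replicate"])
    group_cols = ["source", "dilution"] if per_dilution else ["source"]
    rows = []
    for setting, sub in keys.groupby(group_cols, sort=True):
        members = [trajs[tuple(r)] for r in sub.itertuples(index=False)]
        if len(members) < 3:
            warnings.warn(f"setting {setting}: fewer than 3 trajectories; skipped")
            continue
        dmat = trajectory_dissimilarity_matrix(members)
        ref = representative_trajectory(members, criterion, dmat)
        rows.append(RegimeMetrics(
            setting=setting,
            dDis=dynamic_dispersion(members, ref, dmat),
            dBD=dynamic_beta_diversity(members, dmat),
            dEve=dynamic_evenness(dmat=dmat),
            m=len(members),
            reference_id=ref.replicate_id,
            criterion=criterion,
        ))
    df = pd.DataFrame([vars(r) for r in rows])
    if not df.empty:
        df[group_cols] = pd.DataFrame(df["setting"].tolist(), index=df.index)
        df = df.drop(columns="setting").set_index(group_cols)
    return df
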