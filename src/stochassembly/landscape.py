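"""Maximum-entropy (Ising) energy landscapes over presence/absence states.

A community state is a presence/absence vector sigma in {0,1}^S.  The
pairwise maximum-entropy model assigns

    P(sigma) = exp(-E(sigma)) / Z,
    E(sigma) = -(sum_i h_i sigma_i + sum_{i<j} J_ij sigma_i sigma_j),

so energy is the negative log modelled probability up to the constant
log Z.  Fields h and couplings J are fit either exactly (penalized
likelihood over the 2^S enumeration, S <= 20) or by node-wise logistic
pseudolikelihood for larger systems.  Local minima of E under single-bit
flips define the basins; observed states are assigned to basins by
steepest single-flip descent.  A metric MDS embedding (SMACOF from a
classical-scaling start) provides the 2-D state-space view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import smacof

__all__ = [
    "IsingModel",
    "LandscapeSummary",
    "binarize",
    "fit_ising",
    "energy",
    "find_minima",
    "assign_basin",
    "mmds_embed",
    "framework_split",
]


@dataclass
class IsingModel:
    h: np.ndarray
    J: np.ndarray
    taxa: list = field(default_factory=list)
    mode: str = "exact"
    log_z: float | None = None

    @property
    def n_taxa(self) -> int:
        return self.h.size

    def log_prob(self, state) -> float:
        if self.log_z is None:
            self.log_z = _log_partition(self.h, self.J)
        return -energy(self, state) - self.log_z


@dataclass
class LandscapeSummary:
    local_minima: list              # (state tuple, energy), ascending energy
    basin_assignment: np.ndarray    # index into local_minima per observed state
    embedding: np.ndarray | None = None
    stress: float | None = None


def binarize(counts, detection_threshold: float = 0.001,
             prevalence_bounds=(0.05, 0.95)):
    """Presence/absence at a relative-abundance threshold, dropping
    near-constant taxa (present in <5% or >95% of samples).

    ``counts``: taxa x samples DataFrame (or array).  Returns (binary
    samples x taxa DataFrame, retained taxa, dropped taxa).
    """
    if not (0 <= detection_threshold < 1):
        raise ValueError("detection_threshold must be in [0, 1)")
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(np.asarray(counts))
    rel = df / df.sum(axis=0)
    presence = (rel > detection_threshold).T.astype(int)  # samples x taxa
    prev = presence.mean(axis=0)
    lo, hi = prevalence_bounds
    keep = prev.index[(prev > lo) & (prev < hi)]
    dropped = [t for t in presence.columns if t not in set(keep)]
    if len(keep) < 2:
        raise ValueError("fewer than 2 informative taxa after prevalence filter")
    return presence[keep], list(keep), dropped


def _states_matrix(S: int) -> np.ndarray:
    """All 2^S binary states, one per row."""
    return ((np.arange(2 ** S)[:, None] >> np.arange(S)[None, :]) & 1).astype(float)


def _energies_all(h, J):
    states = _states_matrix(h.size)
    return states, -(states @ h + 0.5 * np.einsum("si,ij,sj->s", states, J, states))


def _log_partition(h, J) -> float:
    _, E = _energies_all(h, J)
    mx = (-E).max()
    return float(mx + np.log(np.exp(-E - mx).sum()))


def fit_ising(binary, mode: str = "exact", l2_penalty: float = 0.01,
              seed=None, max_taxa_exact: int = 15) -> IsingModel:
    """Fit fields and couplings to a samples x taxa presence/absence matrix.

    ``exact``: maximize the average log-likelihood over the full 2^S state
    enumeration with an L2 penalty on J, to gradient norm < 1e-6 (S <= 20;
    when more taxa are supplied the most prevalent informative ones are
    kept up to ``max_taxa_exact``).  ``pseudolikelihood``: one penalized
    logistic fit per taxon, couplings symmetrized as (J + J^T) / 2.
    """
    df = binary if isinstance(binary, pd.DataFrame) else pd.DataFrame(np.asarray(binary))
    X = df.to_numpy(dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("input must be binary presence/absence")
    n, S = X.shape
    if n < 10:
        raise ValueError("need >= 10 samples to fit")
    taxa = list(df.columns)

    if mode == "exact":
        if S > max_taxa_exact:
            prev = X.mean(axis=0)
            order = np.argsort(np.abs(prev - 0.5))[:max_taxa_exact]
            keep = np.sort(order)
            warnings.warn(f"exact mode: keeping {max_taxa_exact} of {S} taxa "
                          "closest to 50% prevalence")
            X, taxa = X[:, keep], [taxa[i] for i in keep]
            S = X.shape[1]
        if S > 20:
            raise ValueError("exact mode limited to 20 taxa")
        return _fit_exact(X, taxa, l2_penalty)
    if mode in ("pseudolikelihood", "pl"):
        return _fit_pseudolikelihood(X, taxa, l2_penalty, seed)
    raise ValueError(f"unknown mode {mode!r}")


def _fit_exact(X, taxa, l2):
    n, S = X.shape
    states = _states_matrix(S)
    iu = np.triu_indices(S, k=1)
    emp_h = X.mean(axis=0)
    emp_J = (X.T @ X / n)[iu]
    pair_states = states[:, iu[0]] * states[:, iu[1]]

    def unpack(theta):
        h = theta[:S]
        J = np.zeros((S, S))
        J[iu] = theta[S:]
        return h, J + J.T

    def negloglik(theta):
        h, J = unpack(theta)
        logw = states @ h + pair_states @ theta[S:]
        mx = logw.max()
        logz = mx + np.log(np.exp(logw - mx).sum())
        ll = emp_h @ h + emp_J @ theta[S:] - logz
        w = np.exp(logw - logz)
        grad_h = emp_h - w @ states
        grad_J = emp_J - w @ pair_states
        pen = l2 * np.sum(theta[S:] ** 2)
        grad = np.concatenate([grad_h, grad_J - 2 * l2 * theta[S:]])
        return -(ll - pen), -grad

    theta0 = np.zeros(S + iu[0].size)
    res = optimize.minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                            options={"gtol": 1e-7, "ftol": 1e-14, "maxiter": 5000})
    if np.linalg.norm(res.jac, ord=np.inf) > 1e-4:  # pragma: no cover
        warnings.warn("exact Ising fit: gradient norm above tolerance")
    h, J = unpack(res.x)
    return IsingModel(h, J, taxa, mode="exact")


def _fit_pseudolikelihood(X, taxa, l2, seed):
    n, S = X.shape
    h = np.zeros(S)
    J = np.zeros((S, S))
    for i in range(S):
        y = X[:, i]
        others = np.delete(np.arange(S), i)
        if y.min() == y.max():
            # taxon constant within this subset: empirical-logit field, no couplings
            ph = np.clip((y.sum() + 0.5) / (n + 1), 1e-6, 1 - 1e-6)
            h[i] = np.log(ph / (1 - ph))
            continue
        clf = LogisticRegression(C=1.0 / max(2 * l2 * n, 1e-12),
                                 solver="lbfgs", max_iter=2000,
                                 random_state=None if seed is None else int(seed))
        clf.fit(X[:, others], y)
        h[i] = clf.intercept_[0]
        J[i, others] = clf.coef_[0]
    J = (J + J.T) / 2.0
    np.fill_diagonal(J, 0.0)
    return IsingModel(h, J, taxa, mode="pseudolikelihood")


def energy(model: IsingModel, state) -> float:
    """E(sigma) = -(h . sigma + sum_{i<j} J_ij sigma_i sigma_j)."""
    s = np.asarray(state, dtype=float).ravel()
    if s.size != model.n_taxa:
        raise ValueError("state length mismatch")
    if not np.isin(s, (0.0, 1.0)).all():
        raise ValueError("state must be binary")
    return float(-(model.h @ s + 0.5 * s @ model.J @ s))


def _delta_energy(model, s):
    # flipping bit i changes sigma_i by delta = 1 - 2 s_i and
    # E by -delta * (h_i + (J s)_i)
    delta = 1.0 - 2.0 * s
    return -delta * (model.h + model.J @ s)


def find_minima(model: IsingModel) -> list:
    """All single-flip local minima, as (state tuple, energy), by energy."""
    S = model.n_taxa
    if S > 20:
        raise ValueError("exhaustive minima enumeration limited to 20 taxa")
    states, E = _energies_all(model.h, model.J)
    # flip deltas for every state at once: dE_i = -(1-2s_i)(h_i + (Js)_i)
    deltas = -(1.0 - 2.0 * states) * (states @ model.J + model.h)
    idx = np.where(np.all(deltas > 0, axis=1))[0]
    minima = [(tuple(int(v) for v in states[k]), float(E[k])) for k in idx]
    minima.sort(key=lambda t: t[1])
    return minima


def assign_basin(model: IsingModel, state, minima=None):
    """Steepest single-flip descent to a local minimum (ties: lowest index).

    Returns the index into ``minima`` (computed if not given).
    """
    if minima is None:
        minima = find_minima(model)
    s = np.asarray(state, dtype=float).copy()
    for _ in range(4 ** model.n_taxa):  # descent terminates well before this
        d = _delta_energy(model, s)
        i = int(np.argmin(d))
        if d[i] > 0:
            break
        s[i] = 1.0 - s[i]
    key = tuple(int(v) for v in s)
    for idx, (st, _) in enumerate(minima):
        if st == key:
            return idx
    raise RuntimeError("descent did not reach a listed minimum")  # pragma: no cover


def summarize_landscape(model: IsingModel, observed_states) -> LandscapeSummary:
    minima = find_minima(model)
    obs = np.asarray(observed_states, dtype=float)
    basins = np.array([assign_basin(model, s, minima) for s in obs])
    return LandscapeSummary(minima, basins)


def mmds_embed(dissimilarity, dims: int = 2, seed=None):
    """Metric MDS by SMACOF from a classical-scaling start.

    Returns (coordinates, stress) with raw stress sum (d - dhat)^2 / 2.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    n = D.shape[0]
    # classical scaling start
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    init = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    coords, stress = smacof(D, n_components=dims, init=init, n_init=1,
                            metric=True, eps=1e-12, max_iter=1000,
                            random_state=None if seed is None else int(seed),
                            normalized_stress=False)
    return coords, float(stress)


def framework_split(table, framework: int) -> dict:
    """Fitting subsets: Framework 1 pools dilutions per source; Framework 2
    keeps each source x dilution inoculum setting separate."""
    meta = table.meta
    for col in ("source", "dilution"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks {col!r}")
    if framework == 1:
        groups = meta.groupby("source", sort=True)
        return {(src,): list(ix) for src, ix in groups.groups.items()}
    if framework == 2:
        groups = meta.groupby(["source", "dilution"], sort=True)
        return {key: list(ix) for key, ix in groups.groups.items()}
    raise ValueError("framework must be 1 or 2")
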