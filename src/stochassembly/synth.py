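"""Synthetic community-assembly experiments.

Generates replicated serial-transfer microbiome experiments with the
statistical structure the analysis pipeline assumes:

1. a species pool with uneven relative abundances and a known total cell
   count in the undiluted suspension,
2. multinomial inoculation at several dilution levels (initial
   stochasticity grows as the founding cell number shrinks),
3. discrete-time generalized Lotka-Volterra dynamics with serial transfers
   every two days and Poisson demographic noise, parameterized so that a
   mutually inhibiting taxon pair forms a bistable attractor motif: which
   member dominates a replicate depends on the founding draw, so alternative
   community states emerge at high dilution,
4. multinomial read sampling per community sample.

All randomness derives from one master seed through
``numpy.random.SeedSequence([seed, source, dilution, replicate])`` so any
single replicate is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from ._containers import CommunityTable

__all__ = [
    "SpeciesPool",
    "ExperimentDesign",
    "DynamicsParams",
    "draw_founding",
    "simulate_dynamics",
    "sequence_sample",
    "generate_dataset",
    "default_pools",
    "default_dynamics",
    "default_design",
]


@dataclass
class SpeciesPool:
    """A source community: taxon labels, composition and suspension size."""

    taxon_ids: list
    rel_abundance: np.ndarray
    total_cells: int
    name: str = "source"

    def __post_init__(self):
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if len(self.taxon_ids) != self.rel_abundance.size:
            raise ValueError("taxon_ids and rel_abundance length mismatch")
        if np.any(self.rel_abundance < 0):
            raise ValueError("relative abundances must be nonnegative")
        if abs(self.rel_abundance.sum() - 1.0) > 1e-9:
            raise ValueError("relative abundances must sum to 1")
        if self.total_cells < 1:
            raise ValueError("total_cells must be >= 1")

    @property
    def n_taxa(self) -> int:
        return self.rel_abundance.size


@dataclass
class ExperimentDesign:
    n_sources: int = 2
    dilution_factors: tuple = (1.0, 0.1, 0.01, 0.001)
    n_replicates: int = 96
    sample_days: tuple = (2, 4, 6, 8)
    seed: int = 0

    def __post_init__(self):
        d = [float(Fraction(x)) for x in self.dilution_factors]
        if any(b >= a for a, b in zip(d, d[1:], strict=False)) and len(d) > 1:
            if not all(b < a for a, b in zip(d, d[1:], strict=False)):
                raise ValueError("dilution_factors must be strictly decreasing")
        self.dilution_factors = tuple(d)
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    @property
    def n_samples(self) -> int:
        return (self.n_sources * len(self.dilution_factors)
                * self.n_replicates * len(self.sample_days))


@dataclass
class DynamicsParams:
    """Parameters of the serial-transfer GLV simulator (rates per day)."""

    growth_rates: np.ndarray
    interaction_matrix: np.ndarray
    transfer_fraction: float = 0.1
    process_noise_sd: float = 0.05
    read_depth: int = 5000
    dt: float = 0.05
    transfer_every: float = 2.0

    def __post_init__(self):
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.interaction_matrix = np.asarray(self.interaction_matrix, dtype=float)
        if not (0 < self.transfer_fraction <= 1):
            raise ValueError("transfer_fraction must be in (0, 1]")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.process_noise_sd < 0:
            raise ValueError("process_noise_sd must be >= 0")
        if not (np.all(np.isfinite(self.growth_rates))
                and np.all(np.isfinite(self.interaction_matrix))):
            raise ValueError("non-finite dynamics parameter")


def draw_founding(pool: SpeciesPool, dilution: float, seed=None) -> np.ndarray:
    """One multinomial founding draw of round(total_cells * dilution) cells."""
    if not (0 < dilution <= 1):
        raise ValueError("dilution must be in (0, 1]")
    n_cells = int(round(pool.total_cells * dilution))
    if n_cells < 1:
        raise ValueError("empty inoculum")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_cells, pool.rel_abundance)


def simulate_dynamics(founding, params: DynamicsParams, days, seed=None) -> np.ndarray:
    """Serial-transfer GLV time series; returns abundances at each requested day.

    Euler integration of dx_i/dt = x_i (r_i - sum_j a_ij x_j); samples are
    taken just before each transfer.  With positive process noise the
    transferred inoculum is Poisson-resampled (demographic drift) and given
    mild lognormal jitter; with process_noise_sd == 0 the run is fully
    deterministic.  Extinct taxa remain at zero.
    """
    x = np.asarray(founding, dtype=float).copy()
    if np.any(x < 0):
        raise ValueError("founding abundances must be nonnegative")
    rng = np.random.default_rng(seed)
    r, A = params.growth_rates, params.interaction_matrix
    days = sorted(days)
    out = np.zeros((len(days), x.size))
    t = 0.0
    next_transfer = params.transfer_every
    for di, day in enumerate(days):
        while t < day - 1e-9:
            step = min(params.dt, day - t, next_transfer - t)
            x = np.maximum(x + step * x * (r - A @ x), 0.0)
            t += step
            if t >= next_transfer - 1e-9 and t < day - 1e-9:
                x = _transfer(x, params, rng)
                next_transfer += params.transfer_every
        out[di] = x
        if abs(t - next_transfer) < 1e-9:
            x = _transfer(x, params, rng)
            next_transfer += params.transfer_every
    return out


def _transfer(x, params, rng):
    kept = params.transfer_fraction * x
    if params.process_noise_sd > 0:
        kept = rng.poisson(kept).astype(float)
        jitter = np.exp(params.process_noise_sd * rng.standard_normal(x.size)
                        - 0.5 * params.process_noise_sd ** 2)
        kept *= jitter
    return kept


def sequence_sample(abundance, read_depth: int, seed=None) -> np.ndarray:
    """Multinomial read draw over relative abundances."""
    a = np.asarray(abundance, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be nonnegative")
    tot = a.sum()
    if tot == 0:
        raise ValueError("all-zero abundance vector")
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(read_depth), a / tot)


def _replicate_seed(master: int, source_i: int, dil_i: int, rep: int):
    return np.random.SeedSequence([int(master), source_i, dil_i, rep])


def generate_dataset(pools, design: ExperimentDesign, params) -> CommunityTable:
    """Full synthetic experiment: one sample per source x dilution x replicate x day.

    ``pools`` and ``params`` may be single objects or per-source sequences.
    """
    if isinstance(pools, SpeciesPool):
        pools = [pools]
    if isinstance(params, DynamicsParams):
        params = [params] * len(pools)
    if len(pools) != design.n_sources or len(params) != design.n_sources:
        raise ValueError("pools/params must match design.n_sources")

    all_taxa = []
    for pool in pools:
        all_taxa.extend(t for t in pool.taxon_ids if t not in all_taxa)
    counts = {}
    meta = []
    for si, (pool, par) in enumerate(zip(pools, params, strict=True)):
        tax_idx = [all_taxa.index(t) for t in pool.taxon_ids]
        for di, dil in enumerate(design.dilution_factors):
            for rep in range(design.n_replicates):
                ss = _replicate_seed(design.seed, si, di, rep)
                rng = np.random.default_rng(ss)
                founding = draw_founding(pool, dil, rng)
                series = simulate_dynamics(founding, par, design.sample_days, rng)
                for day, abund in zip(design.sample_days, series, strict=True):
                    sid = f"{pool.name}_d{di}_r{rep:03d}_t{day}"
                    reads = sequence_sample(abund, par.read_depth, rng)
                    col = np.zeros(len(all_taxa), dtype=int)
                    col[tax_idx] = reads
                    counts[sid] = col
                    meta.append({"sample_id": sid, "source": pool.name,
                                 "dilution": dil, "replicate": rep, "day": day})
    counts = pd.DataFrame(counts, index=all_taxa)
    meta = pd.DataFrame(meta).set_index("sample_id")
    return CommunityTable(counts, meta)


# --- default study conditions -------------------------------------------------

#: Source suspensions emulate one taxon-rich community with a large cell count
#: and one low-diversity community dominated by two competing taxa, so that
#: founding draws at the strongest dilution reach the few-hundred-cell range
#: where multinomial noise can flip the dominant competitor.
_SOIL_TOTAL = 2_590_000
_FRESH_TOTAL = 230_000


def default_pools() -> list:
    """Two synthetic source pools ('soil'-like rich, 'freshwater'-like uneven)."""
    soil_p = np.array([0.20, 0.185, 0.13, 0.10, 0.08, 0.07, 0.06,
                       0.05, 0.04, 0.03, 0.025, 0.03])
    soil = SpeciesPool([f"S{i:03d}" for i in range(1, 13)], soil_p / soil_p.sum(),
                       _SOIL_TOTAL, name="soil")
    fresh_p = np.array([0.30, 0.26, 0.15, 0.10, 0.08, 0.05, 0.035, 0.025])
    fresh = SpeciesPool([f"F{i:03d}" for i in range(1, 9)],
                        fresh_p / fresh_p.sum(), _FRESH_TOTAL, name="freshwater")
    return [soil, fresh]


def default_dynamics(pool: SpeciesPool, carrying_capacity: float = 1e8,
                     read_depth: int = 5000) -> DynamicsParams:
    """Bistable competition motif: taxa 0 and 1 mutually exclude each other.

    Self-limitation sets a shared carrying capacity K.  The focal pair
    inhibits each other strongly (coefficient 2 relative to
    self-limitation), so whichever member leads when the culture saturates
    excludes the other within a few transfer cycles; the remaining taxa
    compete weakly enough to persist alongside the winner, keeping residual
    diversity in every attractor (monodominance with a coexisting tail).
    """
    S = pool.n_taxa
    r = np.full(S, 8.0)
    a = r[0] / carrying_capacity  # self-limitation
    A = np.full((S, S), 0.85 * a)
    np.fill_diagonal(A, a)
    A[0, 1] = A[1, 0] = 2.0 * a          # mutual exclusion pair
    A[2:, :2] = 0.95 * a                 # pair dominates but does not exclude
    A[:2, 2:] = 0.6 * a
    return DynamicsParams(growth_rates=r, interaction_matrix=A,
                          read_depth=read_depth)


def default_design(n_replicates: int = 96, seed: int = 0) -> ExperimentDesign:
    return ExperimentDesign(n_sources=2, dilution_factors=(1.0, 0.1, 0.01, 0.001),
                            n_replicates=n_replicates, sample_days=(2, 4, 6, 8),
                            seed=seed)
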