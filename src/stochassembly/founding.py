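"""Initial stochasticity at inoculation.

When a community is founded by drawing N = round(total_cells * dilution)
cells from a source pool with composition p, the per-taxon founder count is
multinomial, so its coefficient of variation is

    CV_i = sqrt((1 - p_i) / (N p_i)),

which grows as the founding community shrinks.  This module estimates the
CV either analytically or by replicate simulation, applies 16S copy-number
correction to convert read-derived copy counts into cell estimates, and
simulates how many taxa are lost outright at inoculation (expected loss
sum_i (1 - p_i)^N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import SpeciesPool

__all__ = ["FoundingCV", "OTULoss", "founding_cv", "copy_number_correct",
           "simulate_otu_loss"]


@dataclass
class FoundingCV:
    taxon_ids: list
    cv: np.ndarray
    expected_cells: np.ndarray
    n_sim: int
    dilution: float
    below_one_cell: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cv": self.cv, "expected_cells": self.expected_cells,
                             "below_one_cell": self.below_one_cell},
                            index=pd.Index(self.taxon_ids, name="taxon"))


@dataclass
class OTULoss:
    losses: np.ndarray        # taxa lost in each simulated draw
    expected_loss: float      # closed form sum_i (1 - p_i)^N
    n_cells: int


def _n_cells(pool: SpeciesPool, dilution: float) -> int:
    if dilution <= 0 or dilution > 1:
        raise ValueError("dilution must be in (0, 1]")
    n = int(round(pool.total_cells * dilution))
    if n < 1:
        raise ValueError("empty inoculum")
    return n


def founding_cv(pool: SpeciesPool, dilution: float, n_sim: int = 96, seed=None,
                method: str = "simulate") -> FoundingCV:
    """Per-taxon CV of founder cell numbers at one dilution level.

    ``simulate`` draws ``n_sim`` multinomial inoculations and takes the
    empirical CV across them (mirroring replicate plates); ``analytic``
    evaluates sqrt((1-p)/(Np)).  Taxa whose expected founder count is below
    one cell are flagged rather than dropped.
    """
    N = _n_cells(pool, dilution)
    p = pool.rel_abundance
    expected = N * p
    if method == "analytic":
        with np.errstate(divide="ignore"):
            cv = np.where(p > 0, np.sqrt(np.where(p > 0, (1 - p) / (N * p), np.inf)),
                          np.nan)
    elif method == "simulate":
        if n_sim < 2:
            raise ValueError("n_sim must be >= 2 for simulation")
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(N, p, size=n_sim).astype(float)
        mean = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, sd / mean, np.nan)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FoundingCV(list(pool.taxon_ids), cv, expected, n_sim, dilution,
                      below_one_cell=expected < 1, method=method)


def copy_number_correct(counts, copies_per_genome) -> np.ndarray:
    """Convert 16S copy counts to cell estimates: divide and round half-up."""
    x = np.asarray(counts, dtype=float)
    c = np.asarray(copies_per_genome, dtype=float)
    if x.shape[-1] != c.size:
        raise ValueError("counts and copies_per_genome length mismatch")
    if np.any(c < 1):
        raise ValueError("copies_per_genome entries must be >= 1")
    return np.floor(x / c + 0.5).astype(int)


def simulate_otu_loss(pool: SpeciesPool, dilution: float, n_sim: int = 96,
                      seed=None) -> OTULoss:
    """Distribution of the number of taxa receiving zero founder cells."""
    N = _n_cells(pool, dilution)
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(N, pool.rel_abundance, size=n_sim)
    losses = (draws == 0).sum(axis=1)
    expected = float(np.sum((1 - pool.rel_abundance) ** N))
    return OTULoss(losses, expected, N)
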