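"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_META = ("source", "dilution", "replicate", "day")


@dataclass
class CommunityTable:
    """Integer count matrix (taxa x samples) with per-sample metadata.

    ``counts`` columns and ``meta`` index are the sample IDs; metadata carries
    source, dilution, replicate and day for every sample.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        if self.meta.index.duplicated().any():
            dup = self.meta.index[self.meta.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r} in metadata")
        missing = [c for c in self.counts.columns if c not in self.meta.index]
        if missing:
            raise ValueError(f"sample {missing[0]!r} missing from metadata")
        for col in REQUIRED_META:
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        self.meta = self.meta.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("negative counts")
        zero = self.counts.columns[vals.sum(axis=0) == 0]
        if len(zero):
            raise ValueError(f"all-zero sample {zero[0]!r}")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset(self, sample_ids) -> "CommunityTable":
        sample_ids = list(sample_ids)
        return CommunityTable(self.counts[sample_ids], self.meta.loc[sample_ids])

    def settings(self, per_dilution: bool = True):
        """Iterate (key, sub-table) over sources or source x dilution groups."""
        keys = ["source", "dilution"] if per_dilution else ["source"]
        for key, sub in self.meta.groupby(keys, sort=True):
            yield key, self.subset(sub.index)
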