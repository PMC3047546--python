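"""Internal model frame shared by the ANOVA, REML and MCMC fitters.

Maps validated complete-case records onto dense integer index arrays for
the five effect batches and the centered log2-richness covariate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .study_data import PlotRecord, EmptyDataError

#: batch names in model order (residual handled separately everywhere)
BATCHES = (
    "experiment",
    "block",
    "composition",
    "experiment:richness",
    "experiment:composition",
)

#: full source order for variance-component tables
SOURCES = (
    "experiment",
    "block",
    "richness",
    "composition",
    "experiment:richness",
    "experiment:composition",
    "residual",
)


def _dense(keys: list) -> tuple[np.ndarray, list]:
    levels: dict = {}
    idx = np.empty(len(keys), dtype=np.int64)
    for i, key in enumerate(keys):
        idx[i] = levels.setdefault(key, len(levels))
    return idx, list(levels)


@dataclass
class ModelFrame:
    """Index arrays for one dataset, in row order."""

    y: np.ndarray
    x: np.ndarray  # centered log2 richness
    x_center: float
    site_idx: np.ndarray
    block_idx: np.ndarray
    comp_idx: np.ndarray
    pair_idx: np.ndarray  # (site, composition) interaction levels
    site_levels: list
    block_levels: list
    comp_levels: list
    pair_levels: list
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = len(self.y)

    @classmethod
    def from_records(cls, records: Sequence[PlotRecord]) -> "ModelFrame":
        records = list(records)
        if not records:
            raise EmptyDataError("empty record collection")
        if any(r.is_missing for r in records):
            raise ValueError("model frame requires complete cases")
        y = np.array([r.anpp for r in records], dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        logr = np.log2([r.richness for r in records])
        center = float(logr.mean())
        x = logr - center
        site_idx, site_levels = _dense([r.site_id for r in records])
        block_idx, block_levels = _dense([r.global_block for r in records])
        # global codes when assigned, otherwise site-local composition identity
        if all(r.composition_code is not None for r in records):
            comp_keys = [r.composition_code for r in records]
        else:
            comp_keys = [(r.site_id, r.composition_label) for r in records]
        comp_idx, comp_levels = _dense(comp_keys)
        pair_idx, pair_levels = _dense(list(zip(site_idx.tolist(), comp_idx.tolist())))
        return cls(
            y=y,
            x=x,
            x_center=center,
            site_idx=site_idx,
            block_idx=block_idx,
            comp_idx=comp_idx,
            pair_idx=pair_idx,
            site_levels=site_levels,
            block_levels=block_levels,
            comp_levels=comp_levels,
            pair_levels=pair_levels,
        )

    def batch_index(self, name: str) -> tuple[np.ndarray, np.ndarray, int]:
        """Return (level index, per-row coefficient, n levels) for a batch."""
        ones = np.ones(self.n)
        table = {
            "experiment": (self.site_idx, ones, len(self.site_levels)),
            "block": (self.block_idx, ones, len(self.block_levels)),
            "composition": (self.comp_idx, ones, len(self.comp_levels)),
            "experiment:richness": (self.site_idx, self.x, len(self.site_levels)),
            "experiment:composition": (self.pair_idx, ones, len(self.pair_levels)),
        }
        if name not in table:
            raise KeyError(f"unknown batch {name!r}")
        return table[name]

    def z_matrix(self, name: str) -> np.ndarray:
        """Dense indicator (or indicator-times-covariate) design for a batch."""
        idx, coef, nlev = self.batch_index(name)
        Z = np.zeros((self.n, nlev))
        Z[np.arange(self.n), idx] = coef
        return Z
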