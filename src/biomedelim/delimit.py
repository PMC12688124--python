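"""Stacked-model biome delimitation via a Kappa-optimized richness threshold.

Per-species binary maps are summed into a richness surface (s-SDM).  For
each integer threshold t the candidate map (richness >= t) is cross-
tabulated cell-by-cell against a reference biome map, yielding Cohen's
kappa, sensitivity and specificity per threshold.  The delimited biome is
the candidate at the kappa-maximizing threshold (smallest t on ties, i.e.
the most inclusive map; optionally ties break on the true-skill statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import BinaryMap, GridSpec, equal_area_km2
from .metrics import ConfusionCounts, compute_metrics

__all__ = [
    "RichnessMap",
    "ThresholdSweepRow",
    "DelimitationResult",
    "stack_models",
    "sweep_thresholds",
    "select_threshold",
    "delimit",
    "write_sweep_csv",
]


@dataclass
class RichnessMap:
    """Cell-wise species count from stacking binary presence maps."""

    grid: GridSpec
    values: np.ndarray
    n_species: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("richness array shape does not match grid")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > self.n_species):
            raise ValueError("richness must lie in [0, n_species]")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def at_least(self, t: int) -> BinaryMap:
        vals = np.where(np.isnan(self.values), np.nan, (self.values >= t).astype(float))
        return BinaryMap(self.grid, vals)


@dataclass(frozen=True)
class ThresholdSweepRow:
    t: int
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    kappa: float


@dataclass
class DelimitationResult:
    selected_t: int
    map: BinaryMap
    sweep: list[ThresholdSweepRow]
    area_km2: float
    area_fraction: float


def stack_models(maps: Sequence[BinaryMap]) -> RichnessMap:
    """Cell-wise sum of aligned binary maps; no-data wherever any input is."""
    if not maps:
        raise ValueError("need at least one map to stack")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.aligned(grid):
            raise ValueError("maps are not on the same grid")
    cube = np.stack([m.values for m in maps])
    total = cube.sum(axis=0)  # NaN propagates
    return RichnessMap(grid, total, n_species=len(maps))


def sweep_thresholds(
    richness: RichnessMap, reference: BinaryMap
) -> list[ThresholdSweepRow]:
    """Evaluate (richness >= t) against the reference for t = 1..max richness.

    Counts come from the per-cell cross-tabulation over cells valid in both
    maps.  The reference must show both classes there, else kappa is
    undefined for every threshold.
    """
    if not richness.grid.aligned(reference.grid):
        raise ValueError("richness and reference are not on the same grid")
    joint = richness.valid & reference.valid
    if not joint.any():
        raise ValueError("no jointly valid cells")
    ref = reference.values[joint].astype(bool)
    if ref.all() or not ref.any():
        raise ValueError("reference map is single-class; kappa undefined")
    rich = richness.values[joint]
    t_max = int(rich.max())
    rows = []
    for t in range(1, max(t_max, 1) + 1):
        pred = rich >= t
        c = ConfusionCounts(
            tp=int((pred & ref).sum()),
            fp=int((pred & ~ref).sum()),
            tn=int((~pred & ~ref).sum()),
            fn=int((~pred & ref).sum()),
        )
        m = compute_metrics(c)
        rows.append(ThresholdSweepRow(t, c, m.sensitivity, m.specificity, m.kappa))
    return rows


def select_threshold(
    sweep: Sequence[ThresholdSweepRow],
    richness: RichnessMap,
    tiebreak: str = "smallest_t",
) -> tuple[ThresholdSweepRow, BinaryMap]:
    """Pick the kappa-maximizing threshold.

    Ties go to the smallest t (most inclusive map) by default, or, with
    ``tiebreak="tss"``, to the highest sensitivity + specificity - 1 among
    the kappa-tied rows (then smallest t).
    """
    if not sweep:
        raise ValueError("empty threshold sweep")
    best_kappa = max(r.kappa for r in sweep)
    tied = [r for r in sweep if r.kappa == best_kappa]
    if tiebreak == "tss" and len(tied) > 1:
        best_tss = max(r.sensitivity + r.specificity - 1 for r in tied)
        tied = [r for r in tied if r.sensitivity + r.specificity - 1 == best_tss]
    row = min(tied, key=lambda r: r.t)
    return row, richness.at_least(row.t)


def delimit(
    maps: Sequence[BinaryMap],
    reference: BinaryMap,
    tiebreak: str = "smallest_t",
) -> DelimitationResult:
    """Stack, sweep, select and measure: the full delimitation for one roster."""
    if not maps:
        raise ValueError("empty species roster")
    richness = stack_models(maps)
    sweep = sweep_thresholds(richness, reference)
    row, selected = select_threshold(sweep, richness, tiebreak=tiebreak)
    area, fraction = equal_area_km2(selected)
    return DelimitationResult(
        selected_t=row.t,
        map=selected,
        sweep=list(sweep),
        area_km2=area,
        area_fraction=fraction,
    )


def write_sweep_csv(sweep: Sequence[ThresholdSweepRow], path: str | Path) -> Path:
    rows = [
        {
            "t": r.t,
            "TP": r.counts.tp,
            "FP": r.counts.fp,
            "TN": r.counts.tn,
            "FN": r.counts.fn,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "kappa": r.kappa,
        }
        for r in sweep
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
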