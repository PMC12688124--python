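"""Biome-affinity classification of species from record proportions.

Each species is scored by the proportion of its cleaned records falling
inside the reference biome polygon (closed boundary: a record on the edge
counts as inside), then assigned to nested tiers:

* characteristic — >= 50% of records in-biome (majority rule),
* high_affinity  — >= 75%,
* strict         — 100% (strict endemics).

The tiers are nested by construction, so the strict roster is a subset of
the high-affinity roster, which is a subset of the characteristic roster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import PolygonSet
from .occurrences import SpeciesOccurrences

__all__ = ["AffinityAssignment", "classify_affinity", "tier_rosters", "write_assignments_csv"]

TIER_THRESHOLDS: dict[str, float] = {
    "characteristic": 0.50,
    "high_affinity": 0.75,
    "strict": 1.00,
}
TIER_ORDER = ("characteristic", "high_affinity", "strict")


@dataclass(frozen=True)
class AffinityAssignment:
    species: str
    n_records: int
    n_inside: int
    tiers: frozenset[str]

    @property
    def proportion(self) -> float:
        return self.n_inside / self.n_records


def classify_affinity(
    occ: SpeciesOccurrences,
    reference: PolygonSet,
    thresholds: Mapping[str, float] = TIER_THRESHOLDS,
) -> AffinityAssignment:
    """Count in-polygon records and assign every tier whose (inclusive)
    threshold the proportion meets."""
    if len(occ) == 0:
        raise ValueError(f"species {occ.species!r} has no records")
    xy = occ.xy
    if np.isnan(xy).any():
        raise ValueError("affinity requires georeferenced records")
    inside = reference.covers_xy(xy[:, 0], xy[:, 1])
    n_inside = int(inside.sum())
    prop = n_inside / len(occ)
    tiers = frozenset(t for t, thr in thresholds.items() if prop >= thr)
    return AffinityAssignment(occ.species, len(occ), n_inside, tiers)


def tier_rosters(
    assignments: Iterable[AffinityAssignment],
) -> dict[str, list[str]]:
    """Species list per tier, sorted; nested because the tiers are."""
    rosters: dict[str, list[str]] = {t: [] for t in TIER_ORDER}
    for a in assignments:
        for t in a.tiers:
            rosters[t].append(a.species)
    return {t: sorted(sp) for t, sp in rosters.items()}


def write_assignments_csv(
    assignments: Sequence[AffinityAssignment], path: str | Path
) -> Path:
    rows = [
        {
            "species": a.species,
            "n_records": a.n_records,
            "n_inside": a.n_inside,
            "proportion": a.proportion,
            "strict": "strict" in a.tiers,
            "high_affinity": "high_affinity" in a.tiers,
            "characteristic": "characteristic" in a.tiers,
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
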