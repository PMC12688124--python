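"""Occurrence-record cleaning, spatial thinning and the modelling minimum.

The cleaning stage mirrors standard herbarium-record hygiene: drop fossil /
introduced / unidentified material, drop records without coordinates, drop
exact duplicates on (species, locality, collector, date), drop records
outside the study region, and standardize free-text habitat terms to
canonical biome names via a synonym table.  Every rejection is logged with
the criterion that fired.

Thinning enforces a minimum distance between retained localities (default
5 km) to damp spatial autocorrelation: greedy accept after a seeded
shuffle, which yields a maximal set — no rejected record is farther than
the minimum distance from every retained one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import PolygonSet, haversine_km, is_geographic

__all__ = [
    "OccurrenceRecord",
    "SpeciesOccurrences",
    "RejectedRecord",
    "clean_records",
    "thin_occurrences",
    "modelable_species",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "write_rejection_log",
    "read_habitat_synonyms",
]

KNOWN_FLAGS = {"fossil", "introduced", "unidentified"}


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    x: float | None = None
    y: float | None = None
    locality: str = ""
    collector: str = ""
    date: str = ""
    habitat: str = ""
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if (self.x is None) != (self.y is None):
            raise ValueError("x and y must be present together")


@dataclass
class SpeciesOccurrences:
    species: str
    records: list[OccurrenceRecord]

    def __post_init__(self) -> None:
        if any(r.species != self.species for r in self.records):
            raise ValueError("all records must share the set's species")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(r.x, r.y) for r in self.records], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class RejectedRecord:
    record: OccurrenceRecord
    reason: str


def _norm(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


def clean_records(
    records: Iterable[OccurrenceRecord],
    region: PolygonSet | None = None,
    habitat_synonyms: Mapping[str, str] | None = None,
    synonym_table: Mapping[str, str] | None = None,
) -> tuple[dict[str, SpeciesOccurrences], list[RejectedRecord]]:
    """Apply the record-cleaning criteria; return kept sets and a rejection log.

    ``habitat_synonyms`` maps habitat variants (case/whitespace-insensitive)
    to canonical biome names, e.g. 'selva baja caducifolia' -> 'SDTF'.
    ``synonym_table`` optionally maps species names to accepted names and is
    applied verbatim before anything else.  Records whose locality lacks
    coordinates are rejected (reason ``"no coordinates"``) — gazetteer
    georeferencing is out of scope.
    """
    habitat_map = { _norm(k): v for k, v in (habitat_synonyms or {}).items() }
    kept: dict[str, list[OccurrenceRecord]] = {}
    rejected: list[RejectedRecord] = []
    seen: set[tuple[str, str, str, str]] = set()

    for rec in records:
        if synonym_table and rec.species in synonym_table:
            rec = replace(rec, species=synonym_table[rec.species])
        bad_flags = rec.flags & KNOWN_FLAGS
        if bad_flags:
            rejected.append(RejectedRecord(rec, f"flagged: {sorted(bad_flags)[0]}"))
            continue
        if rec.x is None or rec.y is None:
            rejected.append(RejectedRecord(rec, "no coordinates"))
            continue
        if not (np.isfinite(rec.x) and np.isfinite(rec.y)):
            rejected.append(RejectedRecord(rec, "malformed coordinates"))
            continue
        key = (_norm(rec.species), _norm(rec.locality), _norm(rec.collector), _norm(rec.date))
        if key in seen:
            rejected.append(RejectedRecord(rec, "duplicate (locality+collector+date)"))
            continue
        if region is not None and not bool(region.covers_xy(np.array([rec.x]), np.array([rec.y]))[0]):
            rejected.append(RejectedRecord(rec, "outside region"))
            continue
        seen.add(key)
        canon = habitat_map.get(_norm(rec.habitat))
        if canon is not None:
            rec = replace(rec, habitat=canon)
        kept.setdefault(rec.species, []).append(rec)

    return (
        {sp: SpeciesOccurrences(sp, recs) for sp, recs in kept.items()},
        rejected,
    )


def _pairwise_dist_km(xy: np.ndarray, i: int, js: np.ndarray, geographic: bool) -> np.ndarray:
    if geographic:
        return haversine_km(xy[i, 0], xy[i, 1], xy[js, 0], xy[js, 1])
    d = xy[js] - xy[i]
    return np.sqrt((d**2).sum(axis=1))


def thin_occurrences(
    occ: SpeciesOccurrences,
    min_dist_km: float = 5.0,
    seed: int = 0,
    crs_id: str = "ea-km",
) -> SpeciesOccurrences:
    """Greedy spatial thinning to a minimum inter-record distance.

    Shuffles with a fixed seed, then accepts each record whose distance to
    every already-accepted record is >= ``min_dist_km``.  Distances are
    great-circle for a geographic CRS, Euclidean (map units = km) otherwise.
    The result is maximal: every rejected record sits within ``min_dist_km``
    of some retained record.
    """
    n = len(occ.records)
    if n <= 1:
        return SpeciesOccurrences(occ.species, list(occ.records))
    xy = occ.xy
    if np.isnan(xy).any():
        raise ValueError("thinning requires coordinates on every record")
    geographic = is_geographic(crs_id)
    order = np.random.default_rng(seed).permutation(n)
    accepted: list[int] = []
    for i in order:
        if not accepted:
            accepted.append(int(i))
            continue
        d = _pairwise_dist_km(xy, int(i), np.array(accepted), geographic)
        if (d >= min_dist_km).all():
            accepted.append(int(i))
    accepted.sort()
    return SpeciesOccurrences(occ.species, [occ.records[i] for i in accepted])


def modelable_species(
    occ_sets: Mapping[str, SpeciesOccurrences], min_records: int = 5
) -> tuple[dict[str, SpeciesOccurrences], dict[str, SpeciesOccurrences]]:
    """Partition species into modelable (>= min_records) and too-few."""
    modelable = {s: o for s, o in occ_sets.items() if len(o) >= min_records}
    too_few = {s: o for s, o in occ_sets.items() if len(o) < min_records}
    return modelable, too_few


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["species", "x", "y", "locality", "collector", "date", "habitat", "flags"]


def write_occurrences_csv(
    records: Iterable[OccurrenceRecord] | Mapping[str, SpeciesOccurrences],
    path: str | Path,
) -> Path:
    if isinstance(records, Mapping):
        records = [r for occ in records.values() for r in occ.records]
    rows = [
        {
            "species": r.species,
            "x": r.x,
            "y": r.y,
            "locality": r.locality,
            "collector": r.collector,
            "date": r.date,
            "habitat": r.habitat,
            "flags": ";".join(sorted(r.flags)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_occurrences_csv(path: str | Path) -> list[OccurrenceRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        x = float(row.x) if row.x not in ("", "nan") else None
        y = float(row.y) if row.y not in ("", "nan") else None
        flags = frozenset(f for f in str(row.flags).split(";") if f)
        out.append(
            OccurrenceRecord(
                species=row.species, x=x, y=y, locality=row.locality,
                collector=row.collector, date=row.date, habitat=row.habitat,
                flags=flags,
            )
        )
    return out


def write_rejection_log(rejected: Sequence[RejectedRecord], path: str | Path) -> Path:
    rows = [
        {
            "species": r.record.species,
            "locality": r.record.locality,
            "collector": r.record.collector,
            "date": r.record.date,
            "reason": r.reason,
        }
        for r in rejected
    ]
    pd.DataFrame(rows, columns=["species", "locality", "collector", "date", "reason"]).to_csv(
        path, index=False
    )
    return Path(path)


def read_habitat_synonyms(path: str | Path) -> dict[str, str]:
    """Two-column CSV (variant, canonical) -> mapping."""
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
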