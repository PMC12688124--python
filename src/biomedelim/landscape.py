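"""Synthetic landscapes with a known true biome, for end-to-end testing.

Real inputs to a biome-delimitation study — environmental raster stacks,
a reference biome polygon, herbarium occurrence records, independent
validation points — all come from third-party sources.  This module
generates structurally equivalent inputs whose ground truth is known:

* spatially autocorrelated environmental layers (Gaussian-smoothed white
  noise, standardized),
* a "true" biome defined by an explicit threshold rule over those layers
  (e.g. warm AND not-too-wet), vectorized to a reference polygon,
* species occurrence sets with an exactly controlled proportion of records
  inside the biome (the affinity the classifier must recover), sampled
  preferentially from environmentally suitable cells so a suitability
  model can learn the biome,
* mutually exclusive "major biomes" partitioning the landscape, with
  labelled validation points spread across them.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box
from shapely.ops import unary_union

from .grids import (
    BinaryMap,
    GridSpec,
    LabelledPoint,
    PolygonSet,
    RasterLayer,
    write_points,
    write_polygons,
    write_raster,
)
from .occurrences import OccurrenceRecord, SpeciesOccurrences

__all__ = [
    "RuleTerm",
    "BiomeRule",
    "LandscapeConfig",
    "SpeciesSpec",
    "generate_env_stack",
    "true_biome_map",
    "sample_species",
    "partition_biomes",
    "sample_validation_points",
    "write_fixture_dir",
]

# Habitat spellings emitted for in-biome records; the cleaning stage's
# synonym table folds them to the canonical biome name.
HABITAT_VARIANTS = ("dry forest", "BTC", "selva baja caducifolia", "SDTF")
DEFAULT_SYNONYMS = {v: "SDTF" for v in HABITAT_VARIANTS}
_COLLECTORS = ("R. Campos", "M. Salgado", "J. Beltran", "A. Duarte", "L. Chan")


def _round_half_up_int(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class RuleTerm:
    """One clause of a biome rule: layer OP value-at-quantile."""

    layer: str
    op: str  # "ge" (layer >= quantile value) or "le" (layer <= quantile value)
    quantile: float

    def __post_init__(self) -> None:
        if self.op not in ("ge", "le"):
            raise ValueError("op must be 'ge' or 'le'")
        if not 0.0 <= self.quantile <= 1.0:
            raise ValueError("quantile must be in [0, 1]")


@dataclass(frozen=True)
class BiomeRule:
    """Conjunction of threshold clauses over environmental layers.

    The rule's continuous margin (minimum standardized signed distance to
    any clause threshold) doubles as a suitability gradient for sampling.
    """

    terms: tuple[RuleTerm, ...]

    def _layers(self, stack: Sequence[RasterLayer]) -> dict[str, RasterLayer]:
        by_name = {l.name: l for l in stack}
        missing = [t.layer for t in self.terms if t.layer not in by_name]
        if missing:
            raise ValueError(f"rule references unknown layers: {missing}")
        return by_name

    def margin(self, stack: Sequence[RasterLayer]) -> np.ndarray:
        """Min over clauses of (signed distance to threshold) / layer sd."""
        by_name = self._layers(stack)
        margins = []
        for t in self.terms:
            v = by_name[t.layer].values
            thr = float(np.nanquantile(v, t.quantile))
            sd = float(np.nanstd(v)) or 1.0
            m = (v - thr) / sd if t.op == "ge" else (thr - v) / sd
            margins.append(m)
        return np.nanmin(np.stack(margins), axis=0)

    def mask(self, stack: Sequence[RasterLayer]) -> np.ndarray:
        return self.margin(stack) >= 0.0


@dataclass
class LandscapeConfig:
    grid: GridSpec
    n_layers: int = 6
    autocorrelation_scale: float = 8.0
    seed: int = 0
    biome_rule: BiomeRule = field(
        default_factory=lambda: BiomeRule(
            (RuleTerm("env1", "ge", 0.70), RuleTerm("env2", "le", 0.65))
        )
    )
    n_biomes: int = 5
    near_duplicate: bool = False  # append a near-copy of env1, for filter tests

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("need at least two environmental layers")
        if self.n_biomes < 2:
            raise ValueError("need at least two biomes")


def generate_env_stack(config: LandscapeConfig) -> list[RasterLayer]:
    """Standardized, spatially autocorrelated environmental layers.

    Each layer is white noise smoothed by a Gaussian kernel whose width is
    ``autocorrelation_scale`` cells (0 = raw white noise), then z-scored.
    With ``near_duplicate`` an extra layer 'env1_dup' = env1 + small noise
    is appended (rank correlation with env1 > 0.95) to exercise the
    collinearity filter.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid.shape
    layers = []
    for i in range(config.n_layers):
        z = rng.standard_normal(shape)
        if config.autocorrelation_scale > 0:
            z = gaussian_filter(z, sigma=config.autocorrelation_scale, mode="reflect")
        z = (z - z.mean()) / z.std()
        layers.append(RasterLayer(config.grid, z, name=f"env{i + 1}"))
    if config.near_duplicate:
        dup = layers[0].values + 0.1 * rng.standard_normal(shape)
        dup = (dup - dup.mean()) / dup.std()
        layers.append(RasterLayer(config.grid, dup, name="env1_dup"))
    return layers


def _cells_to_polygons(mask: np.ndarray, grid: GridSpec) -> PolygonSet:
    """Dissolved union of the cell rectangles of all True cells (row runs)."""
    boxes = []
    cs = grid.cell_size
    for r in range(grid.n_rows):
        row = mask[r]
        c = 0
        while c < grid.n_cols:
            if row[c]:
                c0 = c
                while c < grid.n_cols and row[c]:
                    c += 1
                x0 = grid.origin_x + c0 * cs
                x1 = grid.origin_x + c * cs
                y1 = grid.origin_y - r * cs
                y0 = grid.origin_y - (r + 1) * cs
                boxes.append(box(x0, y0, x1, y1))
            else:
                c += 1
    return PolygonSet([unary_union(boxes)], crs_id=grid.crs_id)


def true_biome_map(
    stack: Sequence[RasterLayer], rule: BiomeRule
) -> tuple[BinaryMap, PolygonSet]:
    """Evaluate the biome rule and vectorize its footprint to a polygon."""
    grid = stack[0].grid
    mask = rule.mask(stack)
    if not mask.any():
        raise ValueError("biome rule selects no cells (empty biome)")
    return BinaryMap(grid, mask.astype(float)), _cells_to_polygons(mask, grid)


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    n_records: int
    target_affinity: float
    duplicate_rate: float = 0.0
    coordinate_jitter: float = 0.25  # map units; clipped to stay in-cell

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if not 0.0 <= self.target_affinity <= 1.0:
            raise ValueError("target_affinity must be in [0, 1]")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must be in [0, 1]")


def _draw_points_in_cells(
    rng: np.random.Generator,
    cells: np.ndarray,
    n: int,
    weights: np.ndarray | None,
    grid: GridSpec,
    jitter: float,
) -> np.ndarray:
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ValueError("cell weights must be non-negative")
        p = w / w.sum()
    idx = rng.choice(len(cells), size=n, replace=True, p=p)
    rr, cc = cells[idx, 0], cells[idx, 1]
    cs = grid.cell_size
    j = min(jitter, 0.499 * cs)
    xs = grid.origin_x + (cc + 0.5) * cs + rng.uniform(-j, j, n)
    ys = grid.origin_y - (rr + 0.5) * cs + rng.uniform(-j, j, n)
    return np.column_stack([xs, ys])


def sample_species(
    spec: SpeciesSpec,
    biome: BinaryMap,
    stack: Sequence[RasterLayer] | None = None,
    rule: BiomeRule | None = None,
    seed: int = 0,
) -> SpeciesOccurrences:
    """Emit records with an exactly controlled in-biome proportion.

    The in-biome record count is ``round(target_affinity * n_records)``
    (half up) — enforced by stratified sampling, not probabilistically.
    In-biome records are weighted by the biome rule's continuous margin
    when a rule and stack are supplied, so suitable cells receive more
    records and a suitability model can recover the biome.  Duplicates
    (copies of existing rows, sharing locality/collector/date) are
    appended at ``duplicate_rate``.
    """
    rng = np.random.default_rng(seed)
    grid = biome.grid
    n_in = _round_half_up_int(spec.target_affinity * spec.n_records)
    n_out = spec.n_records - n_in
    inside_cells = np.argwhere(biome.ones)
    outside_cells = np.argwhere(biome.valid & ~biome.ones)
    if n_in > 0 and len(inside_cells) == 0:
        raise ValueError("target affinity requires in-biome cells but the biome is empty")
    if n_out > 0 and len(outside_cells) == 0:
        raise ValueError(
            f"target affinity {spec.target_affinity} is impossible: no cells outside the biome"
        )

    w_in = w_out = None
    if stack is not None and rule is not None:
        # Records track the rule's continuous margin on both sides of the
        # boundary: suitable cells inside, environmentally similar
        # "straggler" cells just outside — species have coherent niches.
        # An exponential kernel (scale 0.5 margin-sd units) turns the margin
        # into a relative sampling intensity.
        weight = np.exp(rule.margin(stack) / 0.5)
        if n_in:
            w_in = weight[inside_cells[:, 0], inside_cells[:, 1]]
        if n_out:
            w_out = weight[outside_cells[:, 0], outside_cells[:, 1]]

    pts = []
    if n_in:
        pts.append(
            _draw_points_in_cells(rng, inside_cells, n_in, w_in, grid, spec.coordinate_jitter)
        )
    if n_out:
        pts.append(
            _draw_points_in_cells(rng, outside_cells, n_out, w_out, grid, spec.coordinate_jitter)
        )
    xy = np.vstack(pts)
    in_flags = np.array([True] * n_in + [False] * n_out)

    records = []
    for k, ((x, y), is_in) in enumerate(zip(xy, in_flags)):
        habitat = (
            HABITAT_VARIANTS[int(rng.integers(len(HABITAT_VARIANTS)))]
            if is_in
            else "other vegetation"
        )
        records.append(
            OccurrenceRecord(
                species=spec.name,
                x=float(x),
                y=float(y),
                locality=f"{spec.name}-site-{k:04d}",
                collector=_COLLECTORS[int(rng.integers(len(_COLLECTORS)))],
                date=f"{1980 + int(rng.integers(45))}-{1 + int(rng.integers(12)):02d}-{1 + int(rng.integers(28)):02d}",
                habitat=habitat,
            )
        )
    n_dup = _round_half_up_int(spec.duplicate_rate * spec.n_records)
    for i in rng.choice(spec.n_records, size=n_dup, replace=True):
        records.append(records[int(i)])
    return SpeciesOccurrences(spec.name, records)


def partition_biomes(
    stack: Sequence[RasterLayer],
    target: BinaryMap,
    n_biomes: int = 5,
    target_label: str = "SDTF",
) -> list[tuple[str, BinaryMap]]:
    """Split the landscape into the target biome plus quantile bands of a
    second environmental gradient — mutually exclusive, jointly exhaustive."""
    grid = target.grid
    other = stack[1].values if len(stack) > 1 else stack[0].values
    outside = target.valid & ~target.ones
    qs = np.quantile(other[outside], np.linspace(0, 1, n_biomes)[1:-1]) if n_biomes > 2 else []
    edges = np.concatenate([[-np.inf], np.atleast_1d(qs), [np.inf]])
    out: list[tuple[str, BinaryMap]] = [(target_label, target)]
    for i in range(n_biomes - 1):
        band = outside & (other > edges[i]) & (other <= edges[i + 1])
        out.append((f"biome_{i + 1}", BinaryMap(grid, band.astype(float))))
    return out


def sample_validation_points(
    labelled_maps: Sequence[tuple[str, BinaryMap]],
    n_per_biome: int,
    seed: int = 0,
) -> list[LabelledPoint]:
    """Labelled points, ``n_per_biome`` inside each (mutually exclusive) map."""
    occupancy = np.zeros(labelled_maps[0][1].grid.shape)
    for _, m in labelled_maps:
        occupancy += m.ones
    if occupancy.max() > 1:
        raise ValueError("biome maps overlap; validation labels would be ambiguous")
    rng = np.random.default_rng(seed)
    points: list[LabelledPoint] = []
    for label, m in labelled_maps:
        cells = np.argwhere(m.ones)
        if len(cells) < n_per_biome:
            raise ValueError(
                f"biome {label!r} has {len(cells)} cells, fewer than {n_per_biome} requested points"
            )
        idx = rng.choice(len(cells), size=n_per_biome, replace=False)
        cs = m.grid.cell_size
        for r, c in cells[idx]:
            x = m.grid.origin_x + (c + 0.5) * cs + rng.uniform(-0.25 * cs, 0.25 * cs)
            y = m.grid.origin_y - (r + 0.5) * cs + rng.uniform(-0.25 * cs, 0.25 * cs)
            points.append(LabelledPoint(float(x), float(y), label))
    return points


def write_fixture_dir(
    config: LandscapeConfig,
    species: Sequence[SpeciesSpec],
    outdir: str | Path,
    n_validation_per_biome: int = 200,
) -> dict[str, Path]:
    """Materialize a complete input fixture (rasters, polygons, CSVs)."""
    from .occurrences import write_occurrences_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = generate_env_stack(config)
    biome, polys = true_biome_map(stack, config.biome_rule)
    paths: dict[str, Path] = {}
    for layer in stack:
        paths[layer.name] = write_raster(layer, outdir / f"{layer.name}.asc")
    paths["biome_polygon"] = write_polygons(polys, outdir / "true_biome.geojson")

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.generate_state(len(species) + 1) % (2**31)
    all_records = []
    for sp, s in zip(species, child_seeds[:-1]):
        occ = sample_species(sp, biome, stack, config.biome_rule, seed=int(s))
        all_records.extend(occ.records)
    paths["occurrences"] = write_occurrences_csv(all_records, outdir / "occurrences.csv")

    biomes = partition_biomes(stack, biome, config.n_biomes)
    pts = sample_validation_points(biomes, n_validation_per_biome, seed=int(child_seeds[-1]))
    paths["validation_points"] = write_points(pts, outdir / "validation_points.csv")
    return paths
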