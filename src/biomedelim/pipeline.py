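"""End-to-end orchestration: synth → prep → affinity → sdm → delimit → validate.

Each stage is re-entrant: it reads its inputs from files written by the
previous stage and writes every artifact it produces, so any stage can be
re-run from the manifest alone.  All stochastic stages derive their random
streams from the single run seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import affinity as aff
from . import landscape as ls
from . import metrics as mx
from . import occurrences as oc
from . import sdm
from .delimit import delimit as _delimit_roster
from .delimit import write_sweep_csv
from .grids import (
    BinaryMap,
    GridSpec,
    read_points,
    read_polygons,
    read_raster,
    write_raster,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("synth", "prep", "affinity", "sdm", "delimit", "validate")


@dataclass
class RunConfig:
    """Every tunable constant of the analysis, with the study defaults."""

    outdir: str = "results/run"
    seed: int = 0

    # synthetic landscape
    grid_size: int = 100              # cells per side, 1-km equal-area cells
    n_layers: int = 6
    autocorrelation_scale: float = 8.0
    n_biomes: int = 5
    rule_terms: list = field(
        default_factory=lambda: [["env1", "ge", 0.70], ["env2", "le", 0.65]]
    )
    n_validation_per_biome: int = 200

    # species pool: (count, affinity_low, affinity_high) per band
    species_bands: list = field(
        default_factory=lambda: [
            [6, 1.00, 1.00],   # strict endemics
            [10, 0.75, 0.95],  # high-affinity
            [8, 0.50, 0.70],   # characteristic only
            [6, 0.30, 0.45],   # below every tier
        ]
    )
    records_min: int = 20
    records_max: int = 60
    duplicate_rate: float = 0.10

    # cleaning / thinning / affinity
    thinning_km: float = 5.0
    min_records: int = 5
    tier_thresholds: dict = field(
        default_factory=lambda: {"characteristic": 0.50, "high_affinity": 0.75, "strict": 1.00}
    )

    # modelling
    spearman_cutoff: float = 0.7
    auc_cutoff: float = 0.7
    backend: str = "weighted_logistic"
    background_n: int = 2000
    tiebreak: str = "smallest_t"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return Path(path)

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    def grid(self) -> GridSpec:
        return GridSpec(self.grid_size, self.grid_size, 0.0, float(self.grid_size), 1.0, "ea-km")

    def rule(self) -> ls.BiomeRule:
        return ls.BiomeRule(tuple(ls.RuleTerm(l, op, q) for l, op, q in self.rule_terms))

    def landscape_config(self) -> ls.LandscapeConfig:
        return ls.LandscapeConfig(
            grid=self.grid(),
            n_layers=self.n_layers,
            autocorrelation_scale=self.autocorrelation_scale,
            seed=self.seed,
            biome_rule=self.rule(),
            n_biomes=self.n_biomes,
        )

    def species_pool(self) -> list[ls.SpeciesSpec]:
        rng = np.random.default_rng(self.seed + 101)
        pool = []
        for b, (count, lo, hi) in enumerate(self.species_bands):
            for i in range(count):
                pool.append(
                    ls.SpeciesSpec(
                        name=f"sp_b{b}_{i:02d}",
                        n_records=int(rng.integers(self.records_min, self.records_max + 1)),
                        target_affinity=float(rng.uniform(lo, hi)) if lo < hi else float(lo),
                        duplicate_rate=self.duplicate_rate,
                    )
                )
        return pool


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_synth(cfg: RunConfig) -> dict[str, Path]:
    d = cfg.out / "inputs"
    paths = ls.write_fixture_dir(
        cfg.landscape_config(), cfg.species_pool(), d, cfg.n_validation_per_biome
    )
    return {k: Path(p) for k, p in paths.items()}


def stage_prep(cfg: RunConfig) -> dict[str, Path]:
    d = cfg.out
    records = oc.read_occurrences_csv(d / "inputs" / "occurrences.csv")
    cleaned, rejected = oc.clean_records(records, habitat_synonyms=ls.DEFAULT_SYNONYMS)
    thinned = {
        sp: oc.thin_occurrences(o, cfg.thinning_km, seed=cfg.seed + 7, crs_id="ea-km")
        for sp, o in cleaned.items()
    }
    out = {
        "cleaned": oc.write_occurrences_csv(cleaned, d / "cleaned.csv"),
        "thinned": oc.write_occurrences_csv(thinned, d / "thinned.csv"),
        "rejections": oc.write_rejection_log(rejected, d / "rejections.csv"),
    }
    return out


def _group_by_species(path: Path) -> dict[str, oc.SpeciesOccurrences]:
    records = oc.read_occurrences_csv(path)
    by: dict[str, list] = {}
    for r in records:
        by.setdefault(r.species, []).append(r)
    return {sp: oc.SpeciesOccurrences(sp, rs) for sp, rs in by.items()}


def stage_affinity(cfg: RunConfig) -> dict[str, Path]:
    d = cfg.out
    cleaned = _group_by_species(d / "cleaned.csv")
    reference = read_polygons(d / "inputs" / "true_biome.geojson")
    assignments = [
        aff.classify_affinity(o, reference, cfg.tier_thresholds) for o in cleaned.values()
    ]
    rosters = aff.tier_rosters(assignments)
    (d / "rosters.json").write_text(json.dumps(rosters, indent=1))
    return {
        "assignments": aff.write_assignments_csv(assignments, d / "affinity.csv"),
        "rosters": d / "rosters.json",
    }


def stage_sdm(cfg: RunConfig) -> dict[str, Path]:
    import pandas as pd

    d = cfg.out
    maps_dir = d / "species_maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    thinned = _group_by_species(d / "thinned.csv")
    modelable, _ = oc.modelable_species(thinned, cfg.min_records)
    stack = [read_raster(p) for p in sorted((d / "inputs").glob("env*.asc"))]

    # variable filter at presence + background sample points
    rng = np.random.default_rng(cfg.seed + 13)
    grid = stack[0].grid
    pres_pts = [
        sdm.LabelledPoint(float(x), float(y), "presence")
        for o in modelable.values()
        for x, y in o.xy
    ]
    bg_xy = rng.uniform(size=(500, 2)) * [grid.n_cols * grid.cell_size, grid.n_rows * grid.cell_size]
    bg_pts = [
        sdm.LabelledPoint(grid.origin_x + x, grid.origin_y - y, "background") for x, y in bg_xy
    ]
    selection = sdm.spearman_filter(stack, pres_pts + bg_pts, cfg.spearman_cutoff)
    kept_stack = sdm.subset_stack(stack, selection.kept)
    (d / "variable_selection.json").write_text(
        json.dumps({"kept": selection.kept, "dropped": selection.dropped}, indent=1)
    )

    rows = []
    for i, (sp, occ) in enumerate(sorted(modelable.items())):
        fitted = sdm.fit_suitability(
            occ, kept_stack, background_n=cfg.background_n,
            backend=cfg.backend, seed=cfg.seed + 1000 + i,
        )
        ev = sdm.evaluate_model(fitted, auc_cutoff=cfg.auc_cutoff, seed=cfg.seed + 2000 + i)
        bmap, lpt = sdm.binarize_lpt(fitted, kept_stack)
        if ev.passed:
            write_raster(bmap.as_layer(sp), maps_dir / f"{sp}.asc")
        fitted.to_json(maps_dir / f"{sp}.model.json")
        rows.append(
            {"species": sp, "scheme": ev.scheme, "auc": ev.auc, "lpt": lpt, "passed": ev.passed}
        )
    eval_path = d / "model_evaluation.csv"
    pd.DataFrame(rows).to_csv(eval_path, index=False)
    return {"evaluation": eval_path, "maps_dir": maps_dir, "variables": d / "variable_selection.json"}


def _load_tier_maps(cfg: RunConfig, tier: str) -> list[BinaryMap]:
    d = cfg.out
    rosters = json.loads((d / "rosters.json").read_text())
    maps = []
    for sp in rosters.get(tier, []):
        p = d / "species_maps" / f"{sp}.asc"
        if p.exists():  # absent => failed the AUC gate or below min records
            layer = read_raster(p)
            maps.append(BinaryMap(layer.grid, layer.values))
    return maps


def stage_delimit(cfg: RunConfig) -> dict[str, Path]:
    d = cfg.out
    ref_layer = read_raster(d / "inputs" / "env1.asc")  # grid only
    from .grids import rasterize_polygons

    reference = rasterize_polygons(read_polygons(d / "inputs" / "true_biome.geojson"), ref_layer.grid)
    out: dict[str, Path] = {}
    summary = {}
    for tier in aff.TIER_ORDER:
        maps = _load_tier_maps(cfg, tier)
        if not maps:
            continue
        result = _delimit_roster(maps, reference, tiebreak=cfg.tiebreak)
        write_sweep_csv(result.sweep, d / f"sweep_{tier}.csv")
        write_raster(result.map.as_layer(tier), d / f"delimited_{tier}.asc")
        summary[tier] = {
            "n_species": len(maps),
            "selected_t": result.selected_t,
            "kappa": result.sweep[result.selected_t - 1].kappa,
            "area_km2": result.area_km2,
            "area_fraction": result.area_fraction,
        }
        out[f"map_{tier}"] = d / f"delimited_{tier}.asc"
    (d / "delimitation.json").write_text(json.dumps(summary, indent=1))
    out["summary"] = d / "delimitation.json"
    return out


def stage_validate(cfg: RunConfig, positive_label: str = "SDTF") -> dict[str, Path]:
    d = cfg.out
    points = read_points(d / "inputs" / "validation_points.csv")
    report: dict[str, dict] = {}
    agreement: dict[str, np.ndarray] = {}
    for tier in aff.TIER_ORDER:
        p = d / f"delimited_{tier}.asc"
        if not p.exists():
            continue
        layer = read_raster(p)
        bmap = BinaryMap(layer.grid, layer.values)
        counts, n_excluded = mx.confusion_from_points(points, positive_label, bmap)
        m = mx.compute_metrics(counts)
        report[tier] = {
            "counts": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
            "n_excluded": n_excluded,
            "unrounded": {
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "kappa": m.kappa, "underprediction": m.underprediction,
                "overprediction": m.overprediction,
            },
            "rounded": m.rounded(),
        }
        truth = np.array([pt.label == positive_label for pt in points])
        from .grids import sample_layer

        vals = sample_layer(layer, [pt.x for pt in points], [pt.y for pt in points])
        agreement[tier] = ((vals == 1.0) == truth).astype(float)

    if "high_affinity" in agreement and "characteristic" in agreement:
        w, pval = mx.compare_models_wilcoxon(
            agreement["high_affinity"], agreement["characteristic"]
        )
        report["wilcoxon_high_vs_characteristic"] = {"W": w, "p_value": pval}
    path = d / "validation.json"
    path.write_text(json.dumps(report, indent=1))
    return {"validation": path}


_STAGE_FN = {
    "synth": stage_synth,
    "prep": stage_prep,
    "affinity": stage_affinity,
    "sdm": stage_sdm,
    "delimit": stage_delimit,
    "validate": stage_validate,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write a manifest with file hashes."""
    cfg.out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(cfg.out / "config.yaml")
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    for name in stages:
        t0 = time.perf_counter()
        outputs = _STAGE_FN[name](cfg)
        elapsed = time.perf_counter() - t0
        manifest["stages"][name] = {
            "seconds": round(elapsed, 3),
            "outputs": {
                k: {"path": str(p), "sha256": _sha256(Path(p))}
                for k, p in outputs.items()
                if Path(p).is_file()
            },
        }
    (cfg.out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
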