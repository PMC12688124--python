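"""Per-species suitability modelling: variable filtering, fitting, AUC, LPT.

The pipeline contract is backend-agnostic: a fitted model predicts a
suitability in [0, 1] for any cell with complete environmental values; the
map is binarized at the lowest presence threshold (LPT) — the minimum
predicted suitability over the training presences — which guarantees zero
omission of training records; and performance is the AUC, here the
probability that a held-out presence outranks a background point (ties
count one half), averaged over bootstrap replicates (5–19 records) or
k-fold partitions (>= 20 records).

Two lightweight backends are provided:

* ``envelope`` — a rectilinear percentile envelope scored by a product of
  per-variable triangular kernels (peak at the presence mid-range, decaying
  past the presence extremes);
* ``weighted_logistic`` — presence-vs-background logistic regression on
  linear + quadratic features with balanced class weights, a standard
  approximation to presence-only machine-learning suitability models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .grids import (
    BinaryMap,
    LabelledPoint,
    PolygonSet,
    RasterLayer,
    rasterize_polygons,
    sample_layer,
)
from .occurrences import SpeciesOccurrences

__all__ = [
    "VariableSelection",
    "spearman_filter",
    "subset_stack",
    "split_scheme",
    "fit_suitability",
    "evaluate_model",
    "binarize_lpt",
    "auc_rank",
    "FittedSuitability",
    "ModelEvaluation",
]

BACKENDS = ("envelope", "weighted_logistic")


# ---------------------------------------------------------------------------
# Variable selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableSelection:
    """Outcome of the collinearity filter: kept layers and why others fell."""

    kept: list[str]
    dropped: list[tuple[str, str | None, float]]  # (layer, correlated-with, rho)


def _stack_matrix_at_points(
    stack: Sequence[RasterLayer], xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    return np.column_stack([sample_layer(l, xs, ys) for l in stack])


def spearman_filter(
    stack: Sequence[RasterLayer],
    sample_points: Sequence[LabelledPoint],
    cutoff: float = 0.7,
    presence_label: str = "presence",
) -> VariableSelection:
    """Greedy Spearman collinearity filter at environmental sample points.

    Layers are ranked by |Spearman rho| against the presence indicator (a
    proxy for how much of the species' environmental signal each variable
    carries), ties broken by input order, then retained greedily: a layer is
    dropped if its |rho| with any already-kept layer reaches the cutoff.
    Constant layers are dropped with reason "zero variance".
    """
    if len(stack) < 2:
        raise ValueError("need at least two layers to filter")
    xs = np.array([p.x for p in sample_points])
    ys = np.array([p.y for p in sample_points])
    X = _stack_matrix_at_points(stack, xs, ys)
    y = np.array([p.label == presence_label for p in sample_points], dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    X, y = X[ok], y[ok]
    if len(X) < 10:
        raise ValueError("need >= 10 sample points with complete environmental values")

    names = [l.name for l in stack]
    dropped: list[tuple[str, str | None, float]] = []
    priority: list[tuple[float, int]] = []
    for j, name in enumerate(names):
        if np.std(X[:, j]) == 0.0:
            dropped.append((name, None, float("nan")))
            continue
        rho = stats.spearmanr(X[:, j], y).statistic if np.std(y) > 0 else 0.0
        priority.append((-abs(float(rho)), j))
    priority.sort()

    kept_idx: list[int] = []
    for _, j in priority:
        offender = None
        for k in kept_idx:
            rho = float(stats.spearmanr(X[:, j], X[:, k]).statistic)
            if abs(rho) >= cutoff:
                offender = (names[k], rho)
                break
        if offender is None:
            kept_idx.append(j)
        else:
            dropped.append((names[j], offender[0], offender[1]))
    kept_idx.sort()
    return VariableSelection([names[j] for j in kept_idx], dropped)


def subset_stack(
    stack: Sequence[RasterLayer], kept: Sequence[str]
) -> list[RasterLayer]:
    by_name = {l.name: l for l in stack}
    return [by_name[n] for n in kept]


# ---------------------------------------------------------------------------
# Split rule
# ---------------------------------------------------------------------------


def split_scheme(n_records: int) -> str:
    """Evaluation scheme by sample size: bootstrap for 5–19, k-fold for >= 20."""
    if n_records < 5:
        raise ValueError(f"{n_records} records: below the modelling minimum of 5")
    return "bootstrap" if n_records < 20 else "kfold"


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class _EnvelopeBackend:
    """Product of per-variable triangular kernels around the presence range."""

    def __init__(self) -> None:
        self.mid: np.ndarray | None = None
        self.ext: np.ndarray | None = None

    def fit(self, Xp: np.ndarray, Xb: np.ndarray) -> "_EnvelopeBackend":
        lo = Xp.min(axis=0)
        hi = Xp.max(axis=0)
        self.mid = (lo + hi) / 2
        half = (hi - lo) / 2
        spread = np.vstack([Xp, Xb]).std(axis=0)
        pad = np.maximum(0.5 * spread, 1e-6)  # keeps the kernel finite at lo/hi
        self.ext = half + pad
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        k = np.clip(1.0 - np.abs(X - self.mid) / self.ext, 0.0, 1.0)
        return k.prod(axis=1)

    def params(self) -> dict:
        return {"mid": self.mid.tolist(), "ext": self.ext.tolist()}


class _LogisticBackend:
    """Balanced presence-vs-background logistic fit on linear+quadratic terms."""

    def __init__(self) -> None:
        self.mean: np.ndarray | None = None
        self.sd: np.ndarray | None = None
        self.clf: LogisticRegression | None = None

    @staticmethod
    def _features(X: np.ndarray) -> np.ndarray:
        return np.hstack([X, X**2])

    def fit(self, Xp: np.ndarray, Xb: np.ndarray) -> "_LogisticBackend":
        F = self._features(np.vstack([Xp, Xb]))
        self.mean = F.mean(axis=0)
        self.sd = np.where(F.std(axis=0) == 0, 1.0, F.std(axis=0))
        y = np.r_[np.ones(len(Xp)), np.zeros(len(Xb))]
        self.clf = LogisticRegression(class_weight="balanced", max_iter=500)
        self.clf.fit((F - self.mean) / self.sd, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        F = (self._features(X) - self.mean) / self.sd
        return self.clf.predict_proba(F)[:, 1]

    def params(self) -> dict:
        return {
            "coef": self.clf.coef_.ravel().tolist(),
            "intercept": float(self.clf.intercept_[0]),
            "feature_mean": self.mean.tolist(),
            "feature_sd": self.sd.tolist(),
        }


def _make_backend(name: str):
    if name == "envelope":
        return _EnvelopeBackend()
    if name == "weighted_logistic":
        return _LogisticBackend()
    raise ValueError(f"unknown backend {name!r}; choose from {BACKENDS}")


# ---------------------------------------------------------------------------
# Fitting, evaluation, binarization
# ---------------------------------------------------------------------------


@dataclass
class FittedSuitability:
    """A fitted per-species suitability model plus its training data."""

    species: str
    backend: str
    model: object
    layer_names: list[str]
    Xp: np.ndarray  # presence environmental matrix
    Xb: np.ndarray  # background environmental matrix
    presence_xy: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.model.predict(X), 0.0, 1.0)

    def predict_surface(self, stack: Sequence[RasterLayer]) -> RasterLayer:
        sub = subset_stack(stack, self.layer_names)
        grid = sub[0].grid
        cube = np.stack([l.values for l in sub])
        valid = ~np.isnan(cube).any(axis=0)
        out = np.full(grid.shape, np.nan)
        X = cube[:, valid].T
        out[valid] = self.predict(X)
        return RasterLayer(grid, out, name=f"suitability_{self.species}")

    @property
    def training_summary(self) -> dict[str, int]:
        return {"n_presence": len(self.Xp), "n_background": len(self.Xb)}

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "species": self.species,
            "backend": self.backend,
            "layers": self.layer_names,
            "training_summary": self.training_summary,
            "parameters": self.model.params(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))
        return Path(path)


def _background_cells(
    stack: Sequence[RasterLayer], accessible_area: PolygonSet | None
) -> tuple[np.ndarray, np.ndarray]:
    """(n_cells, n_layers) env matrix of candidate background cells + indices."""
    grid = stack[0].grid
    cube = np.stack([l.values for l in stack])
    valid = ~np.isnan(cube).any(axis=0)
    if accessible_area is not None:
        valid &= rasterize_polygons(accessible_area, grid).ones
    idx = np.argwhere(valid)
    return cube[:, valid].T, idx


def fit_suitability(
    occ: SpeciesOccurrences,
    stack: Sequence[RasterLayer],
    accessible_area: PolygonSet | None = None,
    background_n: int = 10_000,
    backend: str = "weighted_logistic",
    seed: int = 0,
) -> FittedSuitability:
    """Fit a presence-vs-background suitability model for one species.

    Background points are drawn uniformly (without replacement) from the
    cells of the accessible area M with complete environmental values; all
    cells are used when M holds fewer than ``background_n``.
    """
    for layer in stack[1:]:
        if not layer.grid.aligned(stack[0].grid):
            raise ValueError("environmental layers are not aligned")
    xy = occ.xy
    Xp = _stack_matrix_at_points(stack, xy[:, 0], xy[:, 1])
    ok = ~np.isnan(Xp).any(axis=1)
    if not ok.any():
        raise ValueError(f"all presences of {occ.species!r} fall on no-data cells")
    Xp, xy = Xp[ok], xy[ok]
    Xall, _ = _background_cells(stack, accessible_area)
    rng = np.random.default_rng(seed)
    if len(Xall) > background_n:
        Xb = Xall[rng.choice(len(Xall), size=background_n, replace=False)]
    else:
        Xb = Xall
    model = _make_backend(backend).fit(Xp, Xb)
    return FittedSuitability(
        species=occ.species,
        backend=backend,
        model=model,
        layer_names=[l.name for l in stack],
        Xp=Xp,
        Xb=Xb,
        presence_xy=xy,
    )


def auc_rank(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair probability, ties counting one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need scores on both classes")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


@dataclass(frozen=True)
class ModelEvaluation:
    species: str
    auc: float
    scheme: str
    n_replicates: int
    n_skipped: int
    lpt: float
    passed: bool


def _round_half_up_int(x: float) -> int:
    return int(np.floor(x + 0.5))


def evaluate_model(
    fitted: FittedSuitability,
    scheme: str | None = None,
    auc_cutoff: float = 0.7,
    seed: int = 0,
    n_bootstrap: int = 10,
    test_fraction: float = 0.3,
    k_folds: int = 5,
) -> ModelEvaluation:
    """Held-out AUC under the sample-size-dependent resampling scheme.

    Bootstrap: ``n_bootstrap`` replicates of a 70/30 presence split with the
    background resampled per replicate.  K-fold: ``k_folds`` partitions of
    the presences.  Replicates whose test partition holds fewer than two
    presences are skipped and counted.  The LPT comes from the full-data
    fit, not from any replicate.
    """
    n = len(fitted.Xp)
    if scheme is None:
        scheme = split_scheme(n)
    rng = np.random.default_rng(seed)
    clone = _make_backend(fitted.backend)
    aucs: list[float] = []
    skipped = 0

    def one_split(test_idx: np.ndarray) -> None:
        nonlocal skipped
        if len(test_idx) < 2 or n - len(test_idx) < 1:
            skipped += 1
            return
        train = np.setdiff1d(np.arange(n), test_idx)
        Xb = fitted.Xb[rng.choice(len(fitted.Xb), size=len(fitted.Xb), replace=True)]
        m = _make_backend(fitted.backend).fit(fitted.Xp[train], Xb)
        aucs.append(auc_rank(m.predict(fitted.Xp[test_idx]), m.predict(Xb)))

    if scheme == "bootstrap":
        n_test = max(1, _round_half_up_int(test_fraction * n))
        for _ in range(n_bootstrap):
            one_split(rng.permutation(n)[:n_test])
    elif scheme == "kfold":
        for fold in np.array_split(rng.permutation(n), k_folds):
            one_split(fold)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if skipped:
        warnings.warn(
            f"{fitted.species}: {skipped} evaluation partitions skipped "
            "(fewer than 2 test presences)",
            stacklevel=2,
        )
    if not aucs:
        raise ValueError(f"{fitted.species}: no usable evaluation partition")
    auc = float(np.mean(aucs))
    lpt = float(fitted.predict(fitted.Xp).min())
    return ModelEvaluation(
        species=fitted.species,
        auc=auc,
        scheme=scheme,
        n_replicates=len(aucs),
        n_skipped=skipped,
        lpt=lpt,
        passed=auc >= auc_cutoff,
    )


def binarize_lpt(
    fitted: FittedSuitability, stack: Sequence[RasterLayer]
) -> tuple[BinaryMap, float]:
    """Threshold the suitability surface at the lowest presence suitability.

    Every cell with suitability >= LPT becomes 1, so every training presence
    lands on a 1-cell by construction (zero training omission).
    """
    surface = fitted.predict_surface(stack)
    lpt = float(fitted.predict(fitted.Xp).min())
    # small slack: batched prediction over the grid may differ from the
    # presence-matrix prediction in the last float digits
    vals = np.where(
        np.isnan(surface.values), np.nan, (surface.values >= lpt - 1e-9).astype(float)
    )
    return BinaryMap(surface.grid, vals), lpt
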