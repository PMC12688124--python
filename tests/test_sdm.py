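import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from biomedelim.grids import LabelledPoint, RasterLayer
from biomedelim.landscape import SpeciesSpec, sample_species
from biomedelim.sdm import (
    auc_rank,
    binarize_lpt,
    evaluate_model,
    fit_suitability,
    spearman_filter,
    split_scheme,
    subset_stack,
)

from conftest import make_grid


# ---------------------------------------------------------------------------
# split rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(5, "bootstrap"), (19, "bootstrap"), (20, "kfold"), (200, "kfold")])
def test_split_scheme_by_sample_size(n, expected):
    assert split_scheme(n) == expected


def test_split_scheme_below_minimum_raises():
    with pytest.raises(ValueError):
        split_scheme(4)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def brute_force_auc(pos, neg):
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_rank([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_three_of_four_pairs(self):
        assert auc_rank([0.8, 0.4], [0.6, 0.2]) == 0.75

    def test_ties_count_half(self):
        assert auc_rank([0.5], [0.5]) == 0.5

    def test_matches_pair_count_oracle_and_sklearn(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            pos = rng.random(rng.integers(2, 40))
            neg = np.round(rng.random(rng.integers(2, 40)), 1)  # induce ties
            got = auc_rank(pos, neg)
            assert got == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
            y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
            assert got == pytest.approx(roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)


# ---------------------------------------------------------------------------
# Spearman variable filter
# ---------------------------------------------------------------------------

def _layers_from_arrays(grid, named):
    return [RasterLayer(grid, v, name) for name, v in named]


def _sample_points(grid, rng, n=100):
    xs = rng.uniform(0, grid.n_cols, n)
    ys = rng.uniform(0, grid.n_rows, n)
    labels = rng.choice(["presence", "background"], n)
    return [LabelledPoint(x, y, l) for x, y, l in zip(xs, ys, labels)]


class TestSpearmanFilter:
    def test_exact_copy_drops_one(self):
        rng = np.random.default_rng(0)
        grid = make_grid(20, 20)
        a = rng.normal(size=grid.shape)
        stack = _layers_from_arrays(grid, [("A", a), ("B", a.copy())])
        sel = spearman_filter(stack, _sample_points(grid, rng))
        assert len(sel.kept) == 1
        assert {sel.kept[0]} | {d[0] for d in sel.dropped} == {"A", "B"}

    def test_independent_layers_both_kept(self):
        rng = np.random.default_rng(1)
        grid = make_grid(25, 25)
        stack = _layers_from_arrays(
            grid, [("A", rng.normal(size=grid.shape)), ("C", rng.normal(size=grid.shape))]
        )
        sel = spearman_filter(stack, _sample_points(grid, rng))
        assert sorted(sel.kept) == ["A", "C"]

    def test_correlated_pair_plus_independent(self):
        rng = np.random.default_rng(2)
        grid = make_grid(25, 25)
        a = rng.normal(size=grid.shape)
        b = a + 0.3 * rng.normal(size=grid.shape)  # rho ~ 0.95
        c = rng.normal(size=grid.shape)
        sel = spearman_filter(_layers_from_arrays(grid, [("A", a), ("B", b), ("C", c)]),
                              _sample_points(grid, rng, 200))
        assert len(sel.kept) == 2
        assert "C" in sel.kept
        assert len({"A", "B"} & set(sel.kept)) == 1

    def test_constant_layer_dropped_as_zero_variance(self):
        rng = np.random.default_rng(3)
        grid = make_grid(15, 15)
        stack = _layers_from_arrays(
            grid, [("flat", np.ones(grid.shape)), ("A", rng.normal(size=grid.shape)),
                   ("B", rng.normal(size=grid.shape))]
        )
        sel = spearman_filter(stack, _sample_points(grid, rng))
        assert "flat" not in sel.kept
        flat_entry = next(d for d in sel.dropped if d[0] == "flat")
        assert flat_entry[1] is None and np.isnan(flat_entry[2])

    def test_kept_set_satisfies_pairwise_invariant(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        grid = make_grid(30, 30)
        base = rng.normal(size=(3,) + grid.shape)
        named = [("L%d" % i, base[i % 3] + 0.5 * rng.normal(size=grid.shape)) for i in range(8)]
        stack = _layers_from_arrays(grid, named)
        pts = _sample_points(grid, rng, 300)
        sel = spearman_filter(stack, pts, cutoff=0.7)
        by_name = dict(named)
        xs = np.array([p.x for p in pts])
        ys = np.array([p.y for p in pts])
        from biomedelim.grids import sample_layer

        vals = {n: sample_layer(RasterLayer(grid, v, n), xs, ys) for n, v in named}
        for a, b in itertools.combinations(sel.kept, 2):
            assert abs(spearmanr(vals[a], vals[b]).statistic) < 0.7
        for name, offender, rho in sel.dropped:
            if offender is not None:
                assert abs(rho) >= 0.7 and offender in sel.kept


# ---------------------------------------------------------------------------
# Fitting, evaluation, LPT
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_pair(landscape60):
    """Models for a biome-faithful species, one per backend."""
    cfg, stack, biome, _ = landscape60
    occ = sample_species(SpeciesSpec("faithful", 30, 1.0), biome, stack, cfg.biome_rule, seed=5)
    out = {}
    for backend in ("envelope", "weighted_logistic"):
        out[backend] = fit_suitability(occ, stack, background_n=800, backend=backend, seed=11)
    return stack, occ, out


class TestFit:
    def test_prediction_bounded_zero_one(self, fitted_pair):
        stack, occ, models = fitted_pair
        for m in models.values():
            surf = m.predict_surface(stack)
            ok = surf.values[~np.isnan(surf.values)]
            assert ok.min() >= 0.0 and ok.max() <= 1.0

    def test_presences_score_above_background(self, fitted_pair):
        stack, occ, models = fitted_pair
        for m in models.values():
            assert m.predict(m.Xp).mean() > m.predict(m.Xb).mean()

    def test_envelope_single_presence_is_peak(self, landscape60):
        cfg, stack, biome, _ = landscape60
        occ = sample_species(SpeciesSpec("lone", 1, 1.0), biome, seed=3)
        m = fit_suitability(occ, stack, backend="envelope", seed=0)
        assert m.predict(m.Xp)[0] == pytest.approx(1.0)

    def test_same_seed_same_parameters(self, landscape60):
        cfg, stack, biome, _ = landscape60
        occ = sample_species(SpeciesSpec("det", 12, 1.0), biome, seed=4)
        a = fit_suitability(occ, stack, background_n=500, seed=21)
        b = fit_suitability(occ, stack, background_n=500, seed=21)
        assert a.model.params() == b.model.params()

    def test_all_presences_on_nodata_rejected(self, landscape60):
        cfg, stack, biome, _ = landscape60
        hole = [RasterLayer(l.grid, np.where(np.ones(l.grid.shape), l.values, l.values), l.name) for l in stack]
        for l in hole:
            l.values[0:2, 0:2] = np.nan
        occ = sample_species(SpeciesSpec("ghost", 3, 1.0), biome, seed=6)
        for r in occ.records:
            object.__setattr__(r, "x", 0.5)
            object.__setattr__(r, "y", 59.5)
        with pytest.raises(ValueError, match="no-data"):
            fit_suitability(occ, hole, seed=0)


class TestEvaluateAndLPT:
    def test_auc_gate_flag(self, fitted_pair):
        stack, occ, models = fitted_pair
        ev = evaluate_model(models["weighted_logistic"], seed=2)
        assert ev.passed == (ev.auc >= 0.7)
        assert ev.scheme == "kfold"  # 30 records

    def test_learnable_species_has_high_auc(self, fitted_pair):
        stack, occ, models = fitted_pair
        for backend, m in models.items():
            ev = evaluate_model(m, seed=7)
            assert ev.auc > 0.9, backend

    def test_bootstrap_scheme_used_for_small_samples(self, landscape60):
        cfg, stack, biome, _ = landscape60
        occ = sample_species(SpeciesSpec("small", 7, 1.0), biome, stack, cfg.biome_rule, seed=8)
        m = fit_suitability(occ, stack, background_n=400, seed=1)
        ev = evaluate_model(m, seed=1)
        assert ev.scheme == "bootstrap" and ev.n_replicates <= 10

    def test_lpt_is_minimum_presence_suitability(self, fitted_pair):
        stack, occ, models = fitted_pair
        m = models["weighted_logistic"]
        bmap, lpt = binarize_lpt(m, stack)
        assert lpt == pytest.approx(m.predict(m.Xp).min())

    def test_zero_training_omission(self, fitted_pair):
        stack, occ, models = fitted_pair
        for m in models.values():
            bmap, _ = binarize_lpt(m, stack)
            rr, cc, _ = bmap.grid.points_to_cells(m.presence_xy[:, 0], m.presence_xy[:, 1])
            assert (bmap.values[rr, cc] == 1).all()

    def test_constant_surface_binarizes_to_all_ones(self, landscape60):
        cfg, stack, biome, _ = landscape60

        class Flat:
            def predict(self, X):
                return np.full(len(X), 0.4)

        from biomedelim.sdm import FittedSuitability

        occ = sample_species(SpeciesSpec("flat", 5, 1.0), biome, seed=9)
        m = FittedSuitability("flat", "envelope", Flat(), [l.name for l in stack],
                              Xp=np.zeros((5, len(stack))), Xb=np.zeros((10, len(stack))),
                              presence_xy=occ.xy)
        bmap, lpt = binarize_lpt(m, stack)
        assert (bmap.values[bmap.valid] == 1).all()
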