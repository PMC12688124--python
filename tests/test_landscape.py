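import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from biomedelim.grids import rasterize_polygons
from biomedelim.landscape import (
    BiomeRule,
    LandscapeConfig,
    RuleTerm,
    SpeciesSpec,
    generate_env_stack,
    partition_biomes,
    sample_species,
    sample_validation_points,
    true_biome_map,
)

from conftest import make_grid


def neighbor_correlation(values):
    """Correlation between horizontally adjacent cells (a Moran's-I stand-in)."""
    return float(np.corrcoef(values[:, :-1].ravel(), values[:, 1:].ravel())[0, 1])


class TestEnvStack:
    def test_identical_under_same_seed(self):
        cfg = LandscapeConfig(grid=make_grid(30, 30), seed=7)
        a, b = generate_env_stack(cfg), generate_env_stack(cfg)
        for la, lb in zip(a, b):
            assert (la.values == lb.values).all()

    def test_near_duplicate_layer_strongly_rank_correlated(self):
        cfg = LandscapeConfig(grid=make_grid(40, 40), seed=1, near_duplicate=True)
        stack = generate_env_stack(cfg)
        assert stack[-1].name == "env1_dup"
        rho = stats.spearmanr(stack[0].values.ravel(), stack[-1].values.ravel()).statistic
        assert rho > 0.95

    def test_zero_scale_gives_white_noise(self):
        cfg = LandscapeConfig(grid=make_grid(60, 60), seed=2, autocorrelation_scale=0.0)
        stack = generate_env_stack(cfg)
        assert abs(neighbor_correlation(stack[0].values)) < 0.05

    def test_positive_scale_gives_autocorrelation(self):
        cfg = LandscapeConfig(grid=make_grid(60, 60), seed=2, autocorrelation_scale=5.0)
        stack = generate_env_stack(cfg)
        assert neighbor_correlation(stack[0].values) > 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LandscapeConfig(grid=make_grid(5, 5), n_layers=1)


class TestTrueBiome:
    def test_rule_at_minimum_selects_everything(self):
        cfg = LandscapeConfig(grid=make_grid(20, 20), seed=3)
        stack = generate_env_stack(cfg)
        bmap, _ = true_biome_map(stack, BiomeRule((RuleTerm("env1", "ge", 0.0),)))
        assert bmap.values.sum() == 400

    def test_vectorized_outline_rasterizes_back_exactly(self):
        cfg = LandscapeConfig(grid=make_grid(35, 35), seed=4)
        stack = generate_env_stack(cfg)
        bmap, polys = true_biome_map(stack, cfg.biome_rule)
        back = rasterize_polygons(polys, bmap.grid)
        assert (back.values == bmap.values).all()

    def test_single_percentile_rule_fraction(self):
        cfg = LandscapeConfig(grid=make_grid(50, 50), seed=5)
        stack = generate_env_stack(cfg)
        bmap, _ = true_biome_map(stack, BiomeRule((RuleTerm("env1", "ge", 0.70),)))
        frac = bmap.values.mean()
        assert frac == pytest.approx(0.30, abs=0.02)

    def test_empty_biome_raises(self):
        cfg = LandscapeConfig(grid=make_grid(10, 10), seed=6)
        stack = generate_env_stack(cfg)
        impossible = BiomeRule((RuleTerm("env1", "ge", 1.0), RuleTerm("env1", "le", 0.0)))
        with pytest.raises(ValueError, match="empty"):
            true_biome_map(stack, impossible)

    def test_unknown_layer_in_rule_rejected(self):
        cfg = LandscapeConfig(grid=make_grid(10, 10), seed=6)
        stack = generate_env_stack(cfg)
        with pytest.raises(ValueError, match="unknown layers"):
            true_biome_map(stack, BiomeRule((RuleTerm("env99", "ge", 0.5),)))


@pytest.fixture(scope="module")
def biome(landscape60):
    return landscape60[2]


class TestSampleSpecies:

    def test_full_affinity_all_inside(self, biome):
        occ = sample_species(SpeciesSpec("sp", 20, 1.0), biome, seed=0)
        rr, cc, _ = biome.grid.points_to_cells(occ.xy[:, 0], occ.xy[:, 1])
        assert (biome.values[rr, cc] == 1).all()

    def test_rounding_contract_point_eight_of_ten(self, biome):
        occ = sample_species(SpeciesSpec("sp", 10, 0.8), biome, seed=1)
        rr, cc, _ = biome.grid.points_to_cells(occ.xy[:, 0], occ.xy[:, 1])
        assert int(biome.values[rr, cc].sum()) == 8

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=300),
        affinity=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=10),
    )
    def test_realized_affinity_exact_for_any_pool(self, landscape60, n, affinity, seed):
        biome = landscape60[2]
        occ = sample_species(SpeciesSpec("sp", n, affinity), biome, seed=seed)
        assert len(occ) == n
        rr, cc, _ = biome.grid.points_to_cells(occ.xy[:, 0], occ.xy[:, 1])
        assert int(biome.values[rr, cc].sum()) == int(np.floor(affinity * n + 0.5))

    def test_duplicate_rows_share_label_fields(self, biome):
        occ = sample_species(SpeciesSpec("sp", 10, 0.5, duplicate_rate=0.2), biome, seed=2)
        assert len(occ) == 12
        keys = [(r.locality, r.collector, r.date) for r in occ.records]
        assert len(keys) - len(set(keys)) == 2

    def test_determinism(self, biome):
        a = sample_species(SpeciesSpec("sp", 15, 0.6), biome, seed=9)
        b = sample_species(SpeciesSpec("sp", 15, 0.6), biome, seed=9)
        assert a.records == b.records

    def test_impossible_affinity_rejected(self, landscape60):
        cfg, stack, _, _ = landscape60
        all_one, _ = true_biome_map(stack, BiomeRule((RuleTerm("env1", "ge", 0.0),)))
        with pytest.raises(ValueError, match="impossible"):
            sample_species(SpeciesSpec("sp", 10, 0.5), all_one, seed=0)


class TestValidationPoints:
    def test_counts_labels_and_containment(self, landscape60):
        cfg, stack, biome, _ = landscape60
        biomes = partition_biomes(stack, biome, n_biomes=5)
        pts = sample_validation_points(biomes, 50, seed=3)
        assert len(pts) == 5 * 50
        by_label = {}
        for p in pts:
            by_label.setdefault(p.label, []).append(p)
        assert {l: len(v) for l, v in by_label.items()} == {l: 50 for l, _ in biomes}
        for label, bmap in biomes:
            for p in by_label[label]:
                r, c = bmap.grid.point_to_cell(p.x, p.y)
                assert bmap.values[r, c] == 1

    def test_partition_is_exclusive_and_exhaustive(self, landscape60):
        cfg, stack, biome, _ = landscape60
        biomes = partition_biomes(stack, biome, n_biomes=5)
        total = sum(m.ones.sum() for _, m in biomes)
        assert total == biome.valid.sum()

    def test_too_small_biome_rejected(self, landscape60):
        cfg, stack, biome, _ = landscape60
        biomes = partition_biomes(stack, biome, n_biomes=5)
        with pytest.raises(ValueError, match="fewer than"):
            sample_validation_points(biomes, 10_000, seed=0)

    def test_overlapping_maps_rejected(self, landscape60):
        biome = landscape60[2]
        with pytest.raises(ValueError, match="overlap"):
            sample_validation_points([("a", biome), ("b", biome)], 5, seed=0)
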