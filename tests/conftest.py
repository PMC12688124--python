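import numpy as np
import pytest

from biomedelim.grids import BinaryMap, GridSpec, RasterLayer
from biomedelim.landscape import BiomeRule, LandscapeConfig, RuleTerm, generate_env_stack, true_biome_map


def make_grid(n_rows=10, n_cols=10, cell=1.0, crs="ea-km"):
    return GridSpec(n_rows, n_cols, 0.0, n_rows * cell, cell, crs)


def random_binary_map(rng, grid, p=0.5, p_nodata=0.0):
    vals = (rng.random(grid.shape) < p).astype(float)
    if p_nodata:
        vals[rng.random(grid.shape) < p_nodata] = np.nan
    return BinaryMap(grid, vals)


@pytest.fixture(scope="session")
def landscape60():
    """A 60x60 landscape with its environmental stack, biome map and polygon."""
    cfg = LandscapeConfig(grid=make_grid(60, 60), seed=42)
    stack = generate_env_stack(cfg)
    biome, polys = true_biome_map(stack, cfg.biome_rule)
    return cfg, stack, biome, polys
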