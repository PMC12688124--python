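"""Generate the synthetic study system: environmental layers, the true
biome (rule: env1 high AND env2 moderate), a species pool with graded
biome affinities, and multi-biome validation points.

Writes results/run/inputs/.  Usage: python analysis/01_build_landscape.py [seed]
"""

import sys

import pandas as pd

from biomedelim.pipeline import RunConfig, run_pipeline


def main(seed: int = 1) -> None:
    cfg = RunConfig(outdir="results/run", seed=seed)
    run_pipeline(cfg, stages=("synth",))
    occ = pd.read_csv(cfg.out / "inputs" / "occurrences.csv")
    pts = pd.read_csv(cfg.out / "inputs" / "validation_points.csv")
    print(f"landscape: {cfg.grid_size}x{cfg.grid_size} cells, {cfg.n_layers} layers, seed {seed}")
    print(f"species pool: {occ.species.nunique()} species, {len(occ)} raw records")
    print("validation points per biome:")
    print(pts.label.value_counts().to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
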