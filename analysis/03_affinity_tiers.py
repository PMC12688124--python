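"""Classify species into nested biome-affinity tiers by the proportion of
their records inside the reference polygon (>=50% characteristic, >=75%
high-affinity, 100% strict endemic).

Reads results/run/cleaned.csv + the reference polygon; writes affinity.csv
and rosters.json.
"""

import json
import sys

import pandas as pd

from biomedelim.pipeline import RunConfig, run_pipeline


def main(seed: int = 1) -> None:
    cfg = RunConfig(outdir="results/run", seed=seed)
    run_pipeline(cfg, stages=("affinity",))
    table = pd.read_csv(cfg.out / "affinity.csv")
    rosters = json.loads((cfg.out / "rosters.json").read_text())
    print(f"classified {len(table)} species; mean in-biome proportion "
          f"{table.proportion.mean():.2f}")
    for tier in ("strict", "high_affinity", "characteristic"):
        print(f"  {tier:15s}: {len(rosters[tier])} species")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
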