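"""Clean the raw records (duplicates, habitat-term standardization) and
thin each species to >= 5 km between localities.

Reads results/run/inputs/, writes cleaned.csv, thinned.csv, rejections.csv.
"""

import sys

import pandas as pd

from biomedelim.pipeline import RunConfig, run_pipeline


def main(seed: int = 1) -> None:
    cfg = RunConfig(outdir="results/run", seed=seed)
    run_pipeline(cfg, stages=("prep",))
    raw = pd.read_csv(cfg.out / "inputs" / "occurrences.csv")
    cleaned = pd.read_csv(cfg.out / "cleaned.csv")
    thinned = pd.read_csv(cfg.out / "thinned.csv")
    rejections = pd.read_csv(cfg.out / "rejections.csv")
    print(f"raw records:      {len(raw)}")
    print(f"after cleaning:   {len(cleaned)}")
    print(f"after thinning:   {len(thinned)} (>= {cfg.thinning_km} km apart)")
    print("rejections by criterion:")
    print(rejections.reason.value_counts().to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
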