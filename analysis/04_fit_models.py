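"""Fit a suitability model per modelable species (>= 5 thinned records):
Spearman variable filter, presence-vs-background fit, held-out AUC
(bootstrap below 20 records, 5-fold otherwise), LPT binarization.

Writes model_evaluation.csv and per-species maps under species_maps/.
"""

import json
import sys

import pandas as pd

from biomedelim.pipeline import RunConfig, run_pipeline


def main(seed: int = 1) -> None:
    cfg = RunConfig(outdir="results/run", seed=seed)
    run_pipeline(cfg, stages=("sdm",))
    ev = pd.read_csv(cfg.out / "model_evaluation.csv")
    sel = json.loads((cfg.out / "variable_selection.json").read_text())
    print(f"variables kept after Spearman filter (<{cfg.spearman_cutoff}): {sel['kept']}")
    print(f"models fitted: {len(ev)} ({cfg.backend})")
    print(f"AUC gate (>= {cfg.auc_cutoff}): {ev.passed.sum()}/{len(ev)} passed "
          f"({100 * ev.passed.mean():.0f}%), AUC range "
          f"{ev.auc.min():.2f}-{ev.auc.max():.2f}")
    print(ev.groupby("scheme").agg(n=("species", "count"), mean_auc=("auc", "mean")).to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
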