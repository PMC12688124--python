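"""Score each tier's delimited map against the independent multi-biome
validation points: confusion counts, sensitivity, specificity, Cohen's
kappa, under-/overprediction, and a Wilcoxon rank-sum test between the
high-affinity and characteristic maps' per-point agreement.

Writes validation.json.
"""

import json
import sys

from biomedelim.pipeline import RunConfig, run_pipeline


def main(seed: int = 1) -> None:
    cfg = RunConfig(outdir="results/run", seed=seed)
    run_pipeline(cfg, stages=("validate",))
    report = json.loads((cfg.out / "validation.json").read_text())
    for tier in ("strict", "high_affinity", "characteristic"):
        if tier not in report:
            continue
        r = report[tier]["rounded"]
        c = report[tier]["counts"]
        print(f"{tier:15s}: TP={c['tp']:4d} FP={c['fp']:4d} TN={c['tn']:4d} FN={c['fn']:4d} | "
              f"sens {r['sensitivity']:.2f}  spec {r['specificity']:.2f}  "
              f"kappa {r['kappa']:.2f}  under {r['underprediction']:.2f}  "
              f"over {r['overprediction']:.2f}")
    w = report.get("wilcoxon_high_vs_characteristic")
    if w:
        print(f"Wilcoxon high-affinity vs characteristic: W={w['W']:.0f}, p={w['p_value']:.3g}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
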