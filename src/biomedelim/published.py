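"""Published confusion counts for the Mexican SDTF delimitation proposals.

These are the raw TP/FP/TN/FN tallies printed in the study that motivated
this package: ~10,000 independent Asteraceae herbarium points spread over
Mexico's five major biomes, overlaid on candidate seasonally-dry-tropical-
forest (SDTF) maps.  Only the counts are stored — every derived statistic
(sensitivity, specificity, kappa, under-/overprediction) is recomputed by
:func:`biomedelim.metrics.compute_metrics`, never copied from print.  Three
printed cells are internally inconsistent with their own counts; the
recomputed values are the authoritative ones here (see docs/methods.md).
"""

from __future__ import annotations

from .metrics import ConfusionCounts

# Stacked-model evaluation: the three affinity tiers of SDTF endemics,
# scored against the Asteraceae validation points.
STACKING_COUNTS: dict[str, ConfusionCounts] = {
    "strict": ConfusionCounts(tp=808, fp=108, tn=8075, fn=1008),
    "high_affinity": ConfusionCounts(tp=1284, fp=569, tn=7616, fn=532),
    "characteristic": ConfusionCounts(tp=1355, fp=719, tn=7465, fn=461),
}

# Proposal comparison: three previously published SDTF delimitations plus
# the high-affinity stacked model, against the same validation points.
# "vegetation_map" is the delimitation derived from reclassifying Mexico's
# official vegetation cartography (it also serves as the reference polygon
# for threshold selection); "dryflor" is the expert consortium map;
# "prieto_torres" the earlier widespread-species stacking proposal.
PROPOSAL_COUNTS: dict[str, ConfusionCounts] = {
    "dryflor": ConfusionCounts(tp=1362, fp=1230, tn=6954, fn=454),
    "prieto_torres": ConfusionCounts(tp=1560, fp=1108, tn=7076, fn=256),
    "vegetation_map": ConfusionCounts(tp=1721, fp=152, tn=8032, fn=95),
    "high_affinity": ConfusionCounts(tp=1284, fp=569, tn=7616, fn=532),
}
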