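# biomedelim

Delimiting a biome's geographic boundary from the stacked distribution
models of its high-affinity endemic plant species.

Vegetation maps and expert-drawn polygons disagree about where biomes like
Mexico's seasonally dry tropical forest (SDTF) begin and end. An
alternative is to let the flora decide: model the distribution of each
species strongly associated with the biome, stack the binary models into a
richness surface S(x) = Σᵢ ŷᵢ(x), and call "biome" every cell where at
least t species co-occur, with t chosen to maximize Cohen's kappa

    κ = (p_o − p_e) / (1 − p_e),
    p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n²

against a reference map. Species enter nested affinity tiers by the
proportion of their records inside the reference polygon — characteristic
(≥ 50 %), high-affinity (≥ 75 %), strict endemic (100 %) — so the question
"which species delimit best?" becomes a comparison of tiers. Per-species
models are binarized at the lowest presence threshold (LPT), the minimum
predicted suitability at any training record, which guarantees zero
training omission; models are kept only if their held-out AUC ≥ 0.7.
Delimited maps are validated with independent points labelled by biome,
scored by sensitivity, specificity, kappa, underprediction FN/(FN+TN) and
overprediction FP/(FP+TP).

This repository is an analysis project: the library under `src/biomedelim/`
implements every step (occurrence cleaning and 5-km thinning, affinity
tiers, Spearman variable filtering, suitability backends, LPT, stacking,
threshold sweep, validation metrics), the numbered scripts under
`analysis/` run the study on a synthetic landscape with a known true
biome, and `biomedelim` is also a CLI (`synth`, `prep`, `affinity`, `sdm`,
`delimit`, `validate`, `run-all`). Real GBIF/raster inputs are out of
scope; the synthetic generator produces structurally equivalent inputs
with controlled species affinities. See `docs/methods.md` for the model
and its assumptions.

## Worked example

Run the analysis end to end (seed 1):

```
for f in analysis/0*.py; do python "$f" 1; done
```

The drivers populate `results/run/` and print, among other things:

```
models fitted: 30 (weighted_logistic)
AUC gate (>= 0.7): 19/30 passed (63%), AUC range 0.54-0.90

high_affinity  :  15 species stacked, best t=11 (kappa 0.864), area 1866 km^2 = 18.7% of region

high_affinity  : TP= 179 FP=  22 TN= 778 FN=  21 | sens 0.90  spec 0.97  kappa 0.87  under 0.03  over 0.11
Wilcoxon high-affinity vs characteristic: W=1002000, p=0.745

high-affinity  pool: recovery kappa 0.833 at t=24 (30/30 models passed the AUC gate, ...)
low-affinity   pool: recovery kappa 0.562 at t=6 (6/30 models passed the AUC gate, ...)
kappa advantage of the high-affinity pool: +0.271
```

Reading this: of 30 synthetic species, 19 models clear the AUC gate; the
high-affinity tier's richness map agrees best with the truth at a stacking
threshold of 11 co-occurring species, delimiting 18.7 % of the landscape
(the true biome covers 18.8 %); on the 1,000 independent validation points
the delimited map scores kappa 0.87. The final comparison is the headline
result in miniature: a pool of species with ≥ 75 % of records in-biome
recovers the true boundary far better (κ = 0.83) than a pool at 30–50 %
affinity (κ = 0.56).

The same pipeline runs from the shell: `biomedelim run-all --seed 1
--outdir results/run`.

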