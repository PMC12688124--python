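# Methods

## The procedure

`biomedelim` delimits the geographic boundary of a biome from the stacked
distribution models of plant species with high ecological affinity to it
(the motivating case is the seasonally dry tropical forest, SDTF, of
Mexico). The chain is:

1. **Record hygiene.** Herbarium-style occurrence records are cleaned by
   fixed criteria: fossil / introduced / unidentified material dropped;
   records without coordinates dropped (gazetteer georeferencing is out of
   scope — such records are rejected with a dedicated reason code);
   exact duplicates on (species, locality, collector, date) dropped, with
   matching case-insensitive and whitespace-normalized, no fuzzy matching;
   records outside the study region dropped; free-text habitat terms
   ("dry forest", "BTC", "selva baja caducifolia", …) folded to canonical
   biome names by a synonym table. Every rejection is logged with its
   criterion; cleaning is idempotent.
2. **Affinity tiers.** Each species' proportion of cleaned records inside
   the reference biome polygon assigns it to nested tiers:
   *characteristic* (proportion >= 0.50, a majority rule), *high-affinity*
   (>= 0.75), *strict endemic* (= 1.00). Thresholds are inclusive and the
   tiers nest: strict ⊆ high-affinity ⊆ characteristic. Proportions are
   computed on cleaned, pre-thinning records (affinity is a biological
   fidelity measure, thinning a modelling device); a flag switches to
   post-thinning records.
3. **Spatial thinning.** Localities are thinned to a minimum separation of
   5 km (configurable): greedy accept after a seeded shuffle, giving a
   maximal set — every rejected record lies within 5 km of a retained one.
   Distances are great-circle on geographic grids, Euclidean (map units =
   km) on projected ones. Thinning precedes the train/test split.
4. **Suitability models.** Environmental layers are first de-correlated:
   a greedy Spearman filter keeps layers so that all pairwise |rho| < 0.7
   at sample points, processing layers in order of |rho| with the presence
   indicator (ties by input order; constant layers dropped as zero
   variance). Species with >= 5 thinned records are modelled presence vs
   background (background drawn uniformly from the accessible area,
   default 10,000 points or all cells if fewer). Evaluation follows sample
   size: 5–19 records use bootstrap (10 replicates of a 70/30 presence
   split, background resampled per replicate), >= 20 records use 5-fold
   cross-validation. AUC is the probability that a held-out presence
   outranks a background point (ties count ½), averaged over usable
   replicates; replicates with fewer than two test presences are skipped
   and counted. Models with AUC below 0.7 are discarded.
5. **LPT binarization.** Each passing model's surface is thresholded at
   the lowest presence threshold — the minimum predicted suitability over
   the training presences, computed from the full-data fit — so no
   training record is omitted.
6. **Stacking and threshold sweep.** Binary maps of a tier's roster are
   summed cell-wise into a richness surface. For every integer t from 1 to
   the observed maximum richness, the candidate map (richness >= t) is
   cross-tabulated against the reference over jointly valid cells, and
   Cohen's kappa, sensitivity and specificity computed. The delimited
   biome is the candidate with the highest kappa; ties go to the smallest
   t (most inclusive map), or optionally to the highest true-skill
   statistic among the tied rows (`tiebreak="tss"`).
7. **Independent validation.** Labelled points spread over the region's
   major biomes are overlaid on the delimited map; from TP/FP/TN/FN we
   derive sensitivity TP/(TP+FN), specificity TN/(TN+FP), Cohen's kappa
   with the two-class marginal-product chance term
   p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/n²,
   underprediction FN/(FN+TN) (false-omission rate) and overprediction
   FP/(FP+TP) (false-discovery rate). A Wilcoxon rank-sum test compares
   two maps' per-point agreement indicators; since the published analysis
   does not state what vectors were tested, the per-point-indicator
   reading is our documented interpretation.

## Suitability backends

The stacking-and-thresholding contribution is agnostic to the underlying
suitability algorithm, so heavyweight niche-modelling machinery is not
reimplemented. Two interchangeable backends honour the same contract
(suitability in [0, 1] for any cell with complete values):

* `envelope` — a rectilinear presence envelope scored by the product of
  per-variable triangular kernels: peak 1 at the presence mid-range,
  decaying linearly and reaching zero half a pooled standard deviation
  beyond the presence extremes. Transparent and exact for single-presence
  edge cases.
* `weighted_logistic` (default) — logistic regression of presences against
  background on standardized linear + quadratic features with balanced
  class weights, a conventional approximation to presence-only
  machine-learning suitability models.

## The synthetic study system

Real inputs (GBIF records, climate rasters, reference polygons) are
deliberately outside this package's scope, so all end-to-end work runs on
a generated landscape with known truth:

* **Environment.** Six layers of Gaussian-smoothed white noise
  (kernel width 8 cells, z-scored) on a 100×100 grid of 1-km cells in a
  declared equal-area CRS, standing in for climatic/edaphic/topographic
  predictors. Smoothed noise is enough to exercise rank-correlation
  filters and quadratic fits; it makes no claim of climatological realism.
* **True biome.** A conjunction of quantile thresholds on the layers
  (default: env1 above its 70th percentile AND env2 below its 65th),
  covering ~19 % of the landscape, vectorized to a reference polygon whose
  rasterization reproduces the cell mask exactly.
* **Species.** Each species gets an exact in-biome record count,
  round(affinity × n) (half up), enforced by stratified sampling so the
  tier classifier's inputs are deterministic. Record locations on both
  sides of the boundary follow the rule's continuous margin through an
  exponential kernel (scale 0.5 margin-sd units): in-biome records
  concentrate in environmentally suitable cells, out-of-biome records in
  environmentally similar cells near the envelope. Species therefore have
  coherent niches straddling the boundary — as real widespread
  biome-associated taxa do — which is what makes lower-affinity species
  modelable at all rather than environmentally random. Duplicate rows
  (10 % by default) copy locality/collector/date to exercise
  deduplication; habitat strings cycle through the synonym variants.
* **Validation points.** The landscape is partitioned into the target
  biome plus quantile bands of a second gradient (five "major biomes"),
  mutually exclusive and jointly exhaustive; 200 labelled points are drawn
  per biome without replacement of cells.

What passing tests on this system show: the pipeline's bookkeeping,
thresholds and selection logic are correct, and the method recovers a
rule-defined biome from faithful species (pixel kappa ≈ 0.8 for pools at
affinity >= 0.75, versus ≈ 0.4–0.6 for pools at 0.30–0.50). What they do
not show: performance under real spatial sampling bias, taxonomic error,
non-stationary climate gradients, or reference polygons that are
themselves imperfect.

## Numerical choices

* Cell (r, c) center is (origin_x + (c+0.5)·cell, origin_y − (r+0.5)·cell);
  rasterization uses the cell-center rule, and points on polygon
  boundaries count as inside everywhere (closed-set rule).
* No-data is NaN in memory, a sentinel (−9999) on disk, and excluded from
  every confusion matrix and area denominator.
* Areas: equal-area grids with km units give exact cell-count areas;
  geographic grids use the analytic spherical band formula
  R²·Δλ·(sin φ_top − sin φ_bottom). The published national area figure
  depends on an unstated projection, so the area backend is configurable
  and no projection is guessed.
* LPT binarization allows 1e-9 slack below the threshold: batched
  prediction over the grid may differ from prediction over the presence
  matrix in the last float digits, and the zero-omission guarantee must
  survive that.
* Display rounding is half-up to 2 decimals; all internal comparisons use
  unrounded values. Kappa is reported as NaN (with a warning) when a map
  is single-class or chance agreement saturates.
* Random streams: every stochastic stage derives an independent seed from
  the single run seed; fixed seed implies bit-identical artifacts, which
  the manifest's SHA-256 hashes make checkable.

## Published evaluation counts

The package ships the raw TP/FP/TN/FN counts of the published SDTF
evaluation tables (~10,000 Asteraceae points over five Mexican biomes) and
always recomputes statistics from them. Three printed cells are
internally inconsistent with their own counts — the strict-tier
sensitivity (printed 0.45; counts give 808/1816 = 0.4449 → 0.44), the
strict-tier kappa (printed 0.54; counts give 0.5349 → 0.53) and one
proposal's overprediction (printed 0.41; counts give 1108/2668 = 0.4153 →
0.42) — and one statistic is printed differently in the two tables from
identical counts (0.07 vs 0.06; counts give 0.0653 → 0.07). The recomputed
values are authoritative here.

## Known limitations and out-of-scope results

Raster I/O is single-band ESRI ASCII grid with a `.prj` sidecar; polygon
I/O is GeoJSON; no on-the-fly reprojection, multi-band imagery or remote
rasters. Taxonomic name validation and gazetteer georeferencing are not
performed. The published real-data results — 3,673 endemic species, 228
modelled, a 96 % AUC pass rate, per-tier richness maxima and per-threshold
kappa maxima, the 278,581.9 km² (14 %) national area, the map-vs-map kappa
matrix and the W = 48,895,000 rank-sum statistic — depend on GBIF
downloads, national vegetation maps and third-party polygons and are not
reproducible at this package's desk scale; nothing in the test suite
asserts them.
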