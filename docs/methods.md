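# Methods

`timepipe` analyzes segmented single-cell tables from multiplexed
immunofluorescence (MxIF) of tumor-core tissue — here modeled on metastatic
melanoma lymph nodes — and asks whether the spatial organization of the
tumor-immune microenvironment (TIME) differs between patients who recur
after anti-PD1 therapy and those who do not. It operates entirely on
FOV-local pixel coordinates (2040 px ≈ 1 mm; physical units are never
needed) and on per-cell marker intensity means and standard deviations on
the 16-bit scale.

## Phenotyping

Classification is hierarchical. Tier 1 assigns each cell to Tumor, Stroma
or Immune from arcsinh-transformed marker means with a gradient-boosted
tree ensemble (500 estimators, depth 4, learning rate 0.25). Tier 2, an RBF
support-vector classifier behind a standardizer, resolves Immune calls into
nine classes (B cell, cytotoxic T, helper T, Treg, neutrophil, monocyte,
macrophage, dendritic, unclassified immune). Tier 2 never sees Tumor or
Stroma calls, so hierarchical consistency (fine immune label ⇒ broad
Immune) holds by construction rather than by post-hoc repair. Annotations
are split 2/3 train, 1/3 test, stratified on the fine label; a class with a
single annotated example raises an error rather than silently degrading
stratification. Both estimators are pluggable: any scikit-learn classifier
can be substituted, which the test suite uses to keep model-agnostic checks
fast.

## PD1 gating at a fixed false-positive rate

A minority-expressed functional marker is thresholded on two axes — the
cell's intensity mean and its intensity standard deviation — because true
expression raises both the level and the heterogeneity of the signal,
whereas background tends to be uniformly dim.

1. Both axes are arcsinh-transformed with cofactor 1 (`arcsinh(x)`; the
   identity `arcsinh(0)=0` keeps empty cells at zero).
2. Per specimen, the peak (mode) of each axis' distribution — the bulk of
   negative cells — is estimated as the center of the tallest
   Freedman–Diaconis histogram bin and shifted to zero. Both axes are
   shifted by their own specimen mode, making calls invariant to
   per-specimen location offsets (batch effects) on either axis.
3. The pooled shifted values are standardized to zero mean, unit variance.
4. The threshold pair is chosen on annotated negative cells: among
   candidate pairs (empirical quantiles of the negatives per axis), the
   least restrictive pair whose joint exceedance among negatives is at most
   the target FPR. "Least restrictive" is made total by minimizing
   `mean_threshold + sd_threshold` on the standardized scale, ties broken
   toward the lower mean threshold; the search grid is 101 quantiles per
   axis.
5. A cell is positive iff **both** standardized axes exceed their
   thresholds (the AND rule is the stricter, noise-robust combination and
   is the convention throughout this package).

Default target FPR is 0.01. With well-separated mixture components the gate
is conservative: the realized FPR sits at or below target because the joint
exceedance constraint is evaluated empirically.

## Cellular communities (regional scale)

Each cell is summarized by the phenotype composition of its k nearest
neighbors (default k = 75, Euclidean, within the same FOV, excluding the
cell itself; FOVs with ≤ k cells are skipped). Ties at the k-th distance
break by lowest cell id for determinism. Composition vectors are pooled
across the cohort and clustered with mini-batch k-means (batch 1024, up to
100 iterations, 3 k-means++ initializations, seeded); input rows are
canonically sorted by cell id first so results are order-invariant. The
default number of clusters is c = 11, with c = 10 (one per phenotype class
plus one) also natural; both are exposed and `sweep_parameters` reports
inertia and cluster-size entropy over (k, c) grids to support the choice.
Each cluster is labelled by its enriched classes — profile fraction
strictly above 0.10 — in descending order, and summarized per patient as
cluster frequencies (rows sum to 1).

## Index-cell-centric neighborhoods (paracrine scale)

A neighborhood is the closed disc of 57 px diameter (radius 28.5 px,
inclusive boundary) centered on every index cell of a chosen class: TCCN
around tumor cells, CTCN around cytotoxic T cells. Per-class neighbor
counts and per-gated-marker positive counts are tallied; the index cell is
never counted in its own neighborhood. Neighborhoods never cross FOV
boundaries and are truncated at borders without edge correction; a border
flag (index closer than one radius to any FOV edge) is carried in the
output. Analyses typically restrict to populated neighborhoods: TCCN with
at least one immune neighbor, CTCN with at least one tumor neighbor.

## Interaction categories

Each neighborhood falls in exactly one category by the set of distinct
immune classes present among its neighbors: tumor-only (zero immune
neighbors, stroma notwithstanding), homotypic (exactly one class), or
heterotypic (two or more). Presence (≥ 1 cell), not abundance, defines
class membership, and a heterotypic neighborhood with m distinct classes
contributes to all C(m, 2) unordered pairs. Pair and category frequencies
are normalized by the total neighborhoods of the index type in the group
or patient, so category frequencies sum to one and pair frequencies remain
comparable across groups of different sizes. When the index cell is itself
an immune class (CTCN), neighbors of that same class still count as
present.

## Cohort comparison

Features (community frequencies, neighborhood compositions, category and
pairing frequencies, PD1-positive-neighbor fractions) are reduced to
per-patient event counts with a per-patient denominator (cells or
neighborhoods). Group-level 2×2 contingencies are formed by summing counts
within each outcome group and tested with the Pearson chi-squared statistic
(expected counts from margins, no continuity correction); p-values are
adjusted per feature family by Benjamini–Hochberg, with significance
reported at adjusted p < 0.05. Because pooled counts treat neighborhoods as
independent, a patient-level Mann–Whitney comparison of per-patient rates
is reported alongside (`p_rank`) as a sensitivity check against
within-patient correlation. Features whose contingency has a zero margin
are retained with statistic 0 and p = 1, flagged `degenerate`, keeping the
adjustment family stable. Adjustment is applied within each family
(community, TCCN/CTCN composition, TCCN/CTCN category, PD1), which is the
boundary recorded in the comparison table.

## Synthetic tissue generator

The generator emulates the statistical structure the analysis assumes, with
planted ground truth:

- **Cohort design.** Two outcome groups, by default 9 vs 16 patients (a
  typical recurrence split), 16 FOVs per patient, 2040 px square FOVs, and
  ~3,500 cells per FOV of which ~60% are tumor — matching a tumor-core
  census of roughly 1.4 M cells over ~400 FOVs. Validation experiments use
  explicitly smaller cohorts (documented per experiment) so that hundreds
  of replicates run on one CPU.
- **Tumor nests.** A Thomas (parent–offspring) cluster process: Poisson
  parents uniform in the FOV, Poisson offspring displaced by an isotropic
  Gaussian (sd 60 px), offspring outside the FOV discarded. This produces
  the nested, tumor-dominant macro-architecture that community clustering
  should segment.
- **Stroma and immune cells.** Poisson counts per class (thinned Poisson
  process) at the configured proportions, placed by importance resampling of a
  10×-oversampled uniform proposal with weight
  `max(0, 1 + Σ (multiplier − 1) · #nearby attractor cells)` within
  28.5 px. A multiplier of 1 is exactly neutral, > 1 attracts, < 1 repels;
  with no enrichment terms, placement is uniform (complete spatial
  randomness, verified by quadrat tests). The interaction radius equals the
  neighborhood radius so planted effects are directly detectable by the
  TCCN/CTCN analysis. Classes are placed in scheme order (tumor, stroma,
  then immune), so attraction acts from already-placed classes.
- **Markers.** Lineage markers are unimodal per class (high in the marker's
  lineage, low elsewhere) on the arcsinh scale with ~6.7 sd separation by
  default, mapped to the 16-bit scale via `sinh` and clipped. Gated markers
  (PD1) are two-component mixtures on the arcsinh scale with a minority
  positive component restricted to TIL classes by default; the sd channel
  mirrors the mixture with means scaled by 0.6 so positives stand out on
  both gating axes. Each specimen receives a Gaussian location shift
  (sd 0.3) on gated markers, the batch effect the peak alignment must
  remove. Because the generator works on the arcsinh scale, the gating
  transform exactly linearizes the planted mixture.
- **What is not modeled.** No nucleus/cytoplasm geometry, no segmentation
  error, no autofluorescence or spectral bleed-through, no marker
  correlation beyond lineage identity, no spatial intensity gradients
  within an FOV. Passing tests therefore demonstrate the pipeline's
  correctness and sensitivity under the assumed statistical structure, not
  robustness to real imaging artifacts.

## Validation experiments and problem sizes

`timepipe.experiments` bundles the standard checks, also run by
`scripts/acceptance.py`:

- **Oracle equivalence.** k-NN compositions and disc counts match
  quadratic brute-force oracles exactly on 50 random instances of 100–1,000
  cells.
- **Community recovery.** Two planted niches at total-variation distance
  0.8 (2 FOVs per niche, 400 cells each) recovered with ARI ≥ 0.9 at
  k = 75 for every one of 20 seeds.
- **Enrichment power and null calibration.** 20 patients per group, one
  ~750-cell FOV each; dendritic and cytotoxic-T co-attraction to tumor at
  multiplier 3 in one group. Power for both the TCCN dendritic fraction and
  the dendritic–CTL pairing over 100 replicates; false-flag rate over 200
  null replicates compared with 0.05 plus two Monte-Carlo standard
  deviations.
- **Gating calibration.** ~34k cells, planted positive fraction 0.15,
  target FPR 0.01: held-out FPR and absolute error of the recovered
  positive fraction.
- **Classifier sanity.** 4,000 annotations from the default panel: tier-1
  test accuracy, hierarchical consistency, and a permuted-label null. Note
  that an overfit classifier trained on permuted labels has expected
  accuracy between Σ p² and max p of the class frequencies — at or below
  the majority rate, not centered on it — so the null check is one-sided.
- **Statistics.** Exhaustive small 2×2 tables plus random tables against
  the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); BH against hand-applied
  step-up values.
- **Reproducibility.** Two pipeline runs at the same config and seed
  compared byte-for-byte across all CSV outputs.

## Numerical conventions

- Distances are Euclidean in pixels; disc membership is inclusive
  (d ≤ radius) and the radius 28.5 = 57/2 is exactly representable in
  binary floating point, so the boundary convention is exact.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (generator) or `random_state`
  (scikit-learn); identical inputs and seeds give identical outputs, and
  CSV serialization is deterministic (fixed column order, full float
  precision).
- Degenerate inputs fail loudly: expected FOV totals below 10 cells,
  constant markers, missing annotated negatives, singleton annotation
  classes, zero-margin contingencies (at the single-test level) and unknown
  index classes all raise typed exceptions.

## Known limitations

- The pooled-count chi-squared inherits anticonservatism when events are
  strongly spatially correlated within patients; this is visible for
  community-frequency features (cluster membership is highly autocorrelated
  within tumor nests) and is why the rank-based sensitivity p-value is
  reported. Neighborhood-level features are well calibrated in the null
  experiments.
- Mode estimation by histogram bin is robust for the large-n, dominant-peak
  distributions gating targets, but can be noisy for small specimens
  (< a few hundred cells).
- Mini-batch k-means inertia is recomputed on the full data after fitting;
  it is still a local optimum, and the inertia-vs-c diagnostic tolerates
  ~1% mini-batch noise.
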