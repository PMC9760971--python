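# timepipe

Spatial analysis of the tumor-immune microenvironment (TIME) from
multiplexed immunofluorescence single-cell tables.

Per-cell counts of immune subsets often fail to separate patients who
respond to anti-PD1 immunotherapy from those who recur; the discriminating
signal can live in *where* cells sit relative to each other. `timepipe`
implements the spatial analysis ladder for segmented, quantified cell
tables from pathologist-selected tumor-core fields of view (FOVs):

1. **Phenotyping** — a two-tier classifier (gradient-boosted trees for
   Tumor/Stroma/Immune, then an SVM over nine immune classes) from marker
   intensities, plus **PD1 gating**: a dual-axis (mean, sd) threshold on
   arcsinh-transformed intensities, aligned per specimen by peak shifting
   and calibrated to a fixed false-positive rate on annotated negatives.
2. **Cellular communities** (regional scale) — each cell described by the
   phenotype composition of its k = 75 nearest neighbors; composition
   vectors pooled across the cohort and clustered with mini-batch k-means
   into c = 11 community clusters, labelled by their enriched (> 10%)
   classes and summarized as per-patient frequencies.
3. **Cell-centric neighborhoods** (paracrine scale) — closed 57 px
   diameter discs around every tumor cell (TCCN) or cytotoxic T cell
   (CTCN), with per-class neighbor counts.
4. **Interactions** — each neighborhood categorized as tumor-only,
   immune-homotypic (one distinct immune class) or immune-heterotypic
   (≥ 2 classes); heterotypic neighborhoods scored for all unordered
   class pairs; PD1⁺ TIL neighbors counted per class.
5. **Cohort comparison** — per-patient event counts summed per outcome
   group into 2×2 contingencies, Pearson chi-squared (no continuity
   correction), Benjamini–Hochberg adjustment per feature family,
   significance at adjusted p < 0.05, with a rank-based per-patient
   sensitivity p-value alongside.

Because cohorts of this kind are not publicly available, the package ships
a first-class **synthetic tissue generator**: Thomas-process tumor nests,
stroma/immune placement by enrichment-weighted thinning (planting known
group-specific attractions at the 28.5 px interaction radius), and
two-component arcsinh-scale marker mixtures with per-specimen batch
shifts. Every downstream stage is validated against this planted ground
truth; see `docs/methods.md` for the model and its limitations.

## Worked example

Plant a dendritic-cell attraction to tumor (multiplier 3) in the
no-recurrence group only, then ask whether tumor-centric neighborhoods
detect it:

```python
import timepipe
from timepipe import synth, neighborhoods, stats
from timepipe.pipeline import patient_feature_counts

spec = synth.CohortSpec(
    n_patients_per_group=(4, 4),
    group_names=("Recurrence", "NoRecurrence"),
    fovs_per_patient=2,
    tumor_nest_process=synth.NestProcess(parents_per_fov=15, mean_offspring=30),
    interaction_enrichments={("NoRecurrence", "Tumor", "Dendritic"): 3.0},
    seed=11,
)
cells, patients, truth = timepipe.generate_cohort(spec)
cells = timepipe.join_patient_metadata(cells, patients)

tccn = neighborhoods.build_neighborhoods(cells, "Tumor", diameter=57)
populated = neighborhoods.filter_populated(tccn, "Immune")

counts = patient_feature_counts(populated, cells, "composition")
res = stats.compare_groups(counts, patients)
```

Output for the dendritic feature:

```
11614 cells, 16 FOVs, 8 patients
TCCN: 6734 neighborhoods, 1057 with >=1 immune neighbor
contains:Dendritic  NoRecurrence=0.319 Recurrence=0.097  chi2=72.0  p_adj=1.90e-16  direction=NoRecurrence
```

31.9% of immune-populated TCCN in the no-recurrence group contain at least
one dendritic cell versus 9.7% in the recurrence group — the planted
attraction is recovered with the correct direction at adjusted p ≪ 0.05.

The full pipeline (simulate → gate → communities → neighborhoods →
interactions → compare, all outputs as CSV plus run metadata) runs from a
single config:

```sh
timepipe run --seed 0 --out results/
# or stage by stage
timepipe simulate --out data/ --seed 0
timepipe communities --cells data/cells.csv --k 75 --c 11
timepipe neighborhoods --cells data/cells.csv --index-class Tumor --diameter 57
```

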