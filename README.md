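# pcnslkit

Sex-stratified multimodal analysis of primary CNS lymphoma (PCNSL), an
extranodal non-Hodgkin lymphoma confined to the brain and its coverings.
The package implements, as reusable and tested Python, an analysis chain
that integrates digital pathology, MR imaging and clinical data:

- **IHC immune-cell scoring** (`pcnslkit.ihc`) — percent of positively
  stained cells per tissue-microarray core, via Beer–Lambert H-DAB color
  deconvolution, dual Phansalkar + Otsu thresholding, a neighbor-count
  background filter, and distance-transform watershed splitting of
  touching nuclei.
- **Spatial immune heterogeneity** (`pcnslkit.spatial`) — pixel-wise
  percent-positive heatmaps from Gaussian kernel densities over cell
  centroids (σ = 186 µm, 99% of kernel mass inside a 1 mm² circle), plus
  Pearson correlation of immune scores across multisector cores of the
  same tumor.
- **MR volumetrics** (`pcnslkit.mri`) — enhancing / necrotic / edema
  volumes in cm³, focus counting by 26-connectivity, and atlas-overlap
  location percentages including the deep-brain composite (corpus
  callosum, periventricular regions, basal ganglia, thalamus, brainstem,
  cerebellum).
- **Patient clustering** (`pcnslkit.clustering`) — iterative
  random-forest imputation, z-scoring, sex-stratified Ward-linkage
  agglomerative clustering on 11 diagnosis-time features, and cluster
  characterization with ANOVA / Kruskal–Wallis tests.
- **Survival statistics** (`pcnslkit.survival`) — Kaplan–Meier curves and
  log-rank tests on the treated immunocompetent sub-cohort,
  recursive-partitioning style optimal cutoffs (exhaustive maximally
  selected log-rank scan), univariable screening at p < 0.1, backward
  eliminated Cox proportional-hazards models (HR = e^β with Wald 95% CIs),
  and the female-vs-male comparison table (t-test / Mann–Whitney U /
  Fisher's exact by variable type).
- **Synthetic data** (`pcnslkit.synthetic`) — generators for every input
  with known ground truth: stained tiles with planted cell counts,
  multisector core sets with controlled within-tumor heterogeneity,
  3D segmentation volumes on a toy atlas, and cohort tables with planted
  cluster structure and exponential proportional-hazards survival,
  T ~ Exp(h₀·e^{x'β}).

It is written for neuro-oncology and digital-pathology researchers who
want to run the same pipeline on their own cohort tables, tiles and
segmentations — or to study its statistical behavior on synthetic data
with known truth.

## Worked example

`examples/` contains one narrative script per capability. Scoring one
synthetic core (`python examples/01_score_ihc_tile.py`):

```
planted positive fraction : 20.0%
detected DAB+ cells       : 20
detected hematoxylin cells: 81
recovered percent positive: 19.8%
```

The tile was planted with 20 positive among 100 cells; the pipeline
detects 20 DAB+ and 81 hematoxylin+ nuclei (one nucleus was split by the
watershed), recovering 19.8% against the planted 20%.

Survival modelling on a synthetic cohort
(`python examples/06_survival_analysis.py`):

```
survival cohort after filtering: n = 55 of 74
median OS (female): 6.2 months
median OS (male): 12.1 months
variables with log-rank p < 0.1 in any stratum: ['age', 'deep_pct', 'ecog', 'enhancing_cm3', 'foxp3']
eliminated (in order): ['deep_pct', 'enhancing_cm3', 'foxp3']
  age            HR  1.04 (95% CI 1.00-1.07), p = 0.042
  ecog           HR  2.41 (95% CI 1.49-3.90), p = 0.000
```

Rows failing the immune-status/chemotherapy filter are dropped, per-sex
Kaplan–Meier medians are reported, five candidate variables pass the
univariable screen at their per-stratum cutoffs, and backward elimination
retains age and performance status — the two factors the generator's
hazard model weights most strongly.

An end-to-end run (`pcnsl run-all --seed 1 --out demo/` or
`examples/07_full_pipeline.py`) chains synthetic generation, IHC scoring,
spatial statistics, MR features, clustering and survival into a cached,
byte-reproducible `report.json`.

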