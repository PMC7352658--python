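# Methods

This note documents the models, parameter choices and numerical decisions
behind `pcnslkit`, and what the synthetic-data generators do and do not
emulate.

## IHC cell scoring

**Model.** Brightfield H-DAB staining mixes linearly in optical density
(Beer–Lambert): per pixel, OD = c_h·**h** + c_d·**d**, where **h** and
**d** are unit-norm per-channel OD vectors of hematoxylin and DAB. We use
the classical pair **h** ≈ (0.650, 0.704, 0.286), **d** ≈ (0.269, 0.568,
0.778). OD is computed as −log10((I+1)/256): the +1 offset keeps OD
finite at I = 0 and I₀ = 256 maps pure white to exactly zero. Unmixing
projects the OD vector onto the stain basis via the pseudo-inverse of the
3×3 matrix whose third row is the normalized cross product of the two
stain vectors; negative concentrations are clipped to zero. On noiseless
synthetic tiles the render/deconvolve round trip is exact to machine
precision.

**Segmentation.** Each concentration map is thresholded twice and the
results combined with AND: a pixel must pass both the Phansalkar local
threshold (radius 15 px, k = 0.25, p = 2, q = 10, the original
publication's values, computed on the map normalized to [0, 1] with
R = 0.5) and the global Otsu threshold. OR would reduce to whichever
threshold is looser and defeat the purpose of dual thresholding. An
absolute OD floor (`min_od` = 0.15) additionally rejects pixels below
visible staining; without it, a channel containing only acquisition noise
(e.g. the hematoxylin channel of a DAB-only field) would still be split
by Otsu into spurious objects. A constant map has no Otsu threshold and
yields an empty mask with a warning.

**Background filter and splitting.** A pixel is kept only if at least 2
of its 8 neighbors are positive (single pass; the output is always a
subset of the input). The filter acts on pixels, so it is applied to the
mask *before* labelling and watershed — when the stages are listed with
watershed first, a pixel-level rule cannot act there, so the
segment → neighbor filter → watershed → size filter order is fixed.
Touching nuclei are split by watershed on the negated Euclidean distance
transform, seeded by the h-maxima of each object's distance map with
h = 0.3 × that object's maximum distance; per-object h keeps large and
small nuclei on the same footing. Objects below `min_cell_area_px` = 20
(≈ 17 µm² at 0.92 µm/px, below any real nucleus) are discarded.

**Score.** percent_positive = 100·n_dab/(n_dab + n_hema), reading the
hematoxylin count as the negative nuclei. Whether the underlying ratio
should instead be n_dab/n_hema is ambiguous in the field; both are
exposed (`percent_positive`, `ratio_dab_to_hema`) and the fraction-of-all-
cells convention is the default used throughout. A tile with no detected
cells yields an undefined (NaN, flagged) score, never 0.

## Spatial immune maps

Cell-centroid densities are sums of unit-mass isotropic Gaussian kernels,
implemented as impulse images convolved via FFT with a kernel truncated
at 4σ and renormalized to unit sum (O(N log N) at the default
σ = 204 px = 186 µm at 0.92 µm/px). That σ puts
1 − exp(−A/(2πσ²)) = 0.98995 ≈ 99% of a kernel's mass inside a circle of
area 1 mm². Borders are zero-padded; because that attenuates edge
densities, ratio summaries are restricted to pixels at least 2σ from the
border. A pixel enters the percent map only when the denominator
(total-cell) density clears a floor — by default 10% of the slide-median
positive density; an explicit exclusion mask (damaged tissue, artifacts)
is also honored and is a pure restriction, never a renormalization. The
slide-level percent is the ratio of summed valid densities.

Multisector correlation pools all unordered within-patient core pairs
(a 3-core patient contributes 3 pairs; a first-vs-rest pairing is
available by flag) and reports Pearson r with a two-sided t-distribution
p at n_pairs − 2 df; fewer than 3 pairs leaves p undefined.

## MR features

Volumes are voxel counts × voxel volume (mm³ → cm³). Foci are connected
components of the enhancing compartment, 26-connectivity by default
(6 and 18 available). The "main tumor mass" for location percentages is
enhancing + necrosis — the tumor proper, excluding vasogenic edema — with
an enhancing-only flag, since either reading is defensible. Atlas codes
map to frontal/parietal/temporal/occipital/deep/other; where a merged
atlas would give a voxel both a lobar and a deep identity, the code map
must encode the deep code (deep location is the prognostically targeted
variable, so it wins). Inputs must already share one voxel grid;
registration is asserted, not performed.

## Cohort clustering

Sporadically missing entries are filled by iterative chained imputation
with random-forest regressors (each incomplete column regressed on all
others, cycling until change < 1e-3 or 10 rounds), pooled across sexes by
default for more training rows, with a per-stratum flag. Ordinal columns
(ECOG, focus count) are rounded back to their grids; observed entries are
never altered. Features are z-scored with the sample SD (ddof = 1) within
the stratum being clustered; zero-variance features are dropped with a
warning. The 11 clustering features are deep-location %, the three
compartment volumes, focus count, age, ECOG and the four immune scores;
other location percentages are excluded as highly interdependent
(they would dominate the Euclidean metric). ECOG is ordinal in the tests
but numeric in the clustering matrix — Euclidean Ward requires it.

Ward minimum-variance linkage is cut at k clusters; if k is unset, the
largest relative gap between successive merge heights picks k ∈ [2, 6].
Cluster ids are relabelled by decreasing size for determinism. Clusters
smaller than `min_cluster_size` = 4 are flagged excluded — small
satellites are reported, never silently reassigned — and the default
replication configuration (k = 3 per sex) therefore yields three female
clusters and two main male clusters plus an excluded satellite. Cluster
characterization uses one-way ANOVA for numerical and Kruskal–Wallis for
ordinal features, unadjusted p-values with a Benjamini–Hochberg column
alongside.

## Survival analysis

The analysis cohort keeps rows with intact immune status and receipt of
first-line chemotherapy; rows with missing flags are excluded with a
warning. Kaplan–Meier and Cox fits delegate to lifelines (Efron tie
handling; survival time in months, event = death from any cause,
censoring at last follow-up). The optimal cutoff for a numeric variable
is the midpoint between consecutive sorted unique values that maximizes
the two-group log-rank statistic, with at least `min_leaf` = 7 subjects
on either side (the recursive-partitioning default leaf size); ties take
the first value scanning ascending, and a constant variable has no
admissible split. The scan uses an internal vectorized Mantel–Haenszel
statistic for speed, cross-checked against lifelines in the tests. These
maximally selected statistics are inflated relative to prespecified
splits; the screen documents this rather than correcting it, and no
nominal p is attached to the scan statistic itself.

The univariable screen computes each stratum's own cutoff (female, male,
all — matching per-stratum analysis) and selects a variable when its
log-rank p < 0.1 in any stratum. Backward elimination drops the
highest-p Wald term while that p ≥ 0.1; 0.1 retains borderline terms
(e.g. p = 0.091) that a 0.05 rule would discard. Variables can enter
dichotomized at their cutoff (clinical variables such as age > 60,
ECOG > 1) or continuous per unit (immune scores per percentage point,
volumes per cm³). A warning is raised when events fall below 5 per
retained term. The female-vs-male comparison table uses two-sample
t-tests (numerical), Mann–Whitney U (ordinal; normal approximation with
tie correction for n > 20, exact otherwise) and two-sided Fisher's exact
tests (nominal), with mean ± SD / median (IQR) / n (%) descriptives.

## Synthetic data: what it emulates, and what it does not

**Tiles.** Nuclei are ellipses (axis ratio ≤ 1.4, Gaussian-blurred edges,
σ = 1 px) placed by dart throwing with a configurable center-distance
allowance; an infeasible packing raises an explicit error. Negative cells
carry only hematoxylin, positive cells only DAB, at configured OD
amplitudes, plus additive Gaussian OD noise; hard disks are avoided
because they make Otsu degenerate. Tiles are rendered as float RGB so
deconvolution round-trips exactly; quantization to 8-bit happens only on
export. Default pixel size 0.92 µm/px (so 204 px = 186 µm, consistent
with 10× magnification) and ~100 cells per 384² tile. Not emulated:
chromatin texture, stain gradients, scanner color profiles, tissue folds
— so passing recovery tests demonstrates the correctness of the scoring
chain on its own image model, not robustness to histology artifacts.

**Multisector sets.** Planted positive fractions are hierarchical:
patient mean ~ N(0.15, between_sd²), core fraction ~ N(mean, within_sd²),
both clipped to [0.005, 0.95]. The implied pooled core-pair correlation
is between²/(between² + within²), which the correlation tests invert to
plant target regimes. A fraction-level generator is exposed separately so
distributional checks need not render hundreds of tiles.

**Cohorts.** The default configuration reproduces the study conditions:
41 females in three clusters (27% / 17% / 56%: young-small-lesion,
large-tumor, immune-hot/deep) and 33 males in two main clusters plus a
3-patient immune-hot satellite, with ~2-SD separation on the defining
features; sporadic MCAR missingness at 1.1% (9 of 814 feature cells —
the observed sporadic-missingness level; no mechanism beyond MCAR is
implied by single cores floating off or missing charts); survival from an
exponential proportional-hazards model with baseline rate ln2/10.3 per
month (10.3-month median) and log-hazard coefficients applied to z-scored
features (scale-free; 0.5 per SD of age, 0.4 ECOG, 0.3 FoxP3, 0.3
enhancing volume). Administrative censoring uses an independent
exponential with rate h₀·c/(1−c), giving an expected censored fraction c
under β = 0. Treatment flags are independent Bernoulli draws at
population-representative prevalences; they carry no hazard effect, so
the generator cannot (and does not claim to) reproduce treatment-outcome
associations.

**Segmentations.** Spherical foci on a box atlas (four
anterior-posterior lobar slabs split left/right with a central deep box
that overrides them). Overlapping same-compartment foci merge in the
ground truth — the voxel union is what is counted — and a later focus of
a different compartment overwrites earlier voxels. No MR intensities are
simulated; only label volumes are needed downstream.

## Problem sizes and tolerances

The test and acceptance runs use sizes chosen to keep Monte-Carlo error
well below the assertion margins: 20 tiles (5 per planted fraction
{1, 5, 20, 40}%) for scoring recovery (observed MAE ≈ 0.2–0.4 points
against a 2-point bound); n = 2000 for Kaplan–Meier/KS checks; 1000 null
replicates for log-rank type-I error; 40–100 replicates for Cox recovery
(n = 300 per replicate) and pooled-correlation calibration; 15–25
replicates for cutoff recovery (n = 200). Floating-point report output is
serialized at 6 significant digits; all test comparisons use explicit
tolerances, never string equality.

## Known limitations

- The stain matrix is configuration, not estimated from the image;
  strongly miscalibrated scanners would need externally fitted vectors.
- The heatmap validity floor automates the exclusion of low-cellularity
  regions but is not a substitute for manual artifact masking.
- Maximally selected cutoffs inflate type-I error by construction; the
  screen is exploratory, mirroring its intended use.
- k for the cluster cut is a configuration default (height-gap heuristic
  when unset); no consensus/stability machinery is included.
- With ~74 patients, backward-eliminated Cox models are exploratory;
  no internal cross-validation is attempted at this cohort size.
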