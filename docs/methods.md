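# Methods

This note documents the models, numerical choices and limitations of the
plasmavib pipeline, in the order the method runs.

## Data model

One acquisition is a spectrum on a strictly ascending wavenumber grid
(cm⁻¹) with finite intensities in arbitrary units, tagged by patient,
group (cancer / healthy / PCOS), modality (ATR-FTIR / Raman), hydration
(wet / dry) and replicate index. The supervised label is binary:
cancer vs control, where control pools healthy and PCOS participants; the
three-way group is retained for the PCOS sub-analyses. Descending instrument
exports are normalised to ascending on read, so every downstream index
refers to the ascending axis. Duplicate acquisition keys are read errors,
never silently averaged — replicate averaging is an explicit pipeline stage.

## Synthetic plasma spectra

No public raw-spectra deposit exists for this study design, so the generator
emulates the *statistical* structure the analysis depends on, not plasma
radiative physics.

**Cohort and latent score.** 54 patients (22 cancer, 18 PCOS, 14 healthy)
by default. Each patient has a latent disease score *d*: cancer 1, healthy
0, PCOS drawn from Uniform(0, 1). This one device generates all three
qualitative phenomena the analysis should reproduce: supervised
separability, PCOS spectra overlapping both poles in unsupervised PCA, and
a PCOS centroid between the healthy and cancer centroids. Demographics
(age, BMI category, blood-pressure status) are sampled to loosely mirror a
surgical endometrial-cancer cohort (cancer mean age 63 SD 10; controls
mean 39 SD 13) and are carried as metadata only.

**Signal model.** A spectrum is a sum of Gaussian bands (centre, SD,
amplitude) at canonical plasma positions — for ATR-FTIR the lipid ester
C=O at 1733 cm⁻¹, the Amide I complex (1635–1695), Amide II (1545),
CH₂/CH₃ deformations, Amide III and PO₂⁻ bands; for Raman Amide I,
carotenoids (1525), the CH₂ deformation anchor at 1450, Amide III,
nucleic-acid PO₂ bands and phenylalanine (1004). Band amplitude responds
linearly to *d* through a signed per-band class effect; the 1733 cm⁻¹
lipid band carries the strongest planted effect and serves as the biomarker
recovery target. The 1450 cm⁻¹ Raman band is deliberately class-free
because it is the area-normalisation anchor. Gaussian (not Voigt) line
shapes: every downstream operator is line-shape-agnostic.

**Noise structure** (all relative SDs on band amplitudes):

| source | default | scope |
| --- | --- | --- |
| biological heterogeneity | 0.055 | per patient × band × modality, shared by that patient's replicates |
| acquisition drift | 0.07 | per acquisition × band (contact/focus variability) |
| additive noise | 0.01 a.u. | per point |
| water band (wet ATR-FTIR) | amplitude 1.2 at 1637 cm⁻¹, SD 60 cm⁻¹; ±30 % per-acquisition jitter; −2 % per replicate dehydration decay | per acquisition |
| coffee-ring site factor | 0.15 multiplicative | per dry replicate |
| baseline | random quadratic, coefficient SD 0.08 | per acquisition |

The split between patient-level and acquisition-level variability is the
load-bearing design choice. Patient-level noise caps attainable
patient-level accuracy and keeps the classes overlapping; acquisition-level
noise penalises per-spectrum evaluation of single modalities but is
suppressed by the replicate averaging that precedes fusion. That is the
mechanism by which the fused representation outperforms each wet single
modality here — consistent with the interpretation that wet-sample
acquisition variability (dehydration during the ~11 min of acquisition)
limits single-modality performance. The two noise SDs were calibrated once
so the pipeline operates in the realistic ~0.75–0.90 accuracy regime
rather than at a separable ceiling, and then frozen.

**What the generator does not emulate:** Mie scattering and fluorescence
backgrounds, EMSC-type multiplicative chemistry, instrument line-shape
functions, wavenumber-calibration error, correlated biology across
modalities (band perturbations are independent between ATR-FTIR and Raman),
and any real biochemical covariance structure. Passing tests therefore show
that the *pipeline* behaves correctly under a plausible data-generating
process; they are not evidence about real plasma spectra.

## Pre-processing

Stage order for ATR-FTIR: truncate to 1800–900 cm⁻¹ → (optional)
atmospheric-gas correction → AsLS baseline → vector normalisation. For
Raman: truncate to 1800–750 cm⁻¹ → rubber-band baseline → CH₂-band area
normalisation (single-modality analysis) or vector normalisation (fusion).
Truncation intervals are closed.

**AsLS.** The Eilers–Boelens asymmetric-least-squares estimator: minimise
Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)², w starting at 1 and refreshed to p = 0.05 above
the baseline and 1−p below, λ = 1000, at most 10 iterations with an early
stop at a weight fixed point. The pentadiagonal normal equations are solved
with a banded Cholesky factorisation; tests pin the banded solver to a dense
direct solve of the same iteration to 1e-8 on random spectra. AsLS is not
exactly idempotent: re-applying it to an already-corrected spectrum removes
a further few percent of smooth band mass, which is inherent to the
estimator; the test suite bounds rather than denies this.

**Rubber band.** The baseline is the lower convex hull of (grid, intensity),
built by a monotone-chain scan and evaluated by linear interpolation between
hull vertices; the corrected spectrum is ≥ 0 everywhere and exactly 0 at
hull vertices (both endpoints included). Tests require exact agreement with
an O(n²) brute-force hull. Unlike AsLS this operator *is* idempotent, and
the Raman stack (rubber band + area normalisation) passes a second
application unchanged.

**Atmospheric correction.** The platform correction the workflow emulates
is a built-in with no published algorithm, so a minimal testable stand-in is
used: subtract non-negative multiples of vapor and CO₂ reference spectra
chosen to minimise the first-difference roughness of the corrected spectrum
(2-column NNLS). It is optional and skipped when no references are supplied,
as for synthetic data (the generator plants no atmospheric lines).

**Band integral.** Trapezoidal on the native grid, with the band edges
(1378.1 and 1490.1 cm⁻¹ by default) entered by linear interpolation. The
"kept constant" target value is 1.0 by convention; every classifier and
statistic downstream is invariant to that choice.

## Fusion

Replicates are averaged per patient per modality, each averaged block is
re-normalised to unit Euclidean norm, and the blocks are concatenated
FTIR-first. Averaging (rather than pairing acquisitions across modalities)
avoids arbitrary cross-pairings and patient-count inflation; re-normalising
keeps both blocks on the same intensity scale, which is the point of the
pre-concatenation vector normalisation. A patient missing either modality
is a hard error listing the patient, never a silent drop.

## Supervised evaluation

Patients — never spectra — are allocated to 70 % training / 30 % testing,
stratified by class (per-class floors plus largest-remainder rounding,
remainders to the larger class; 54 patients → 38 train / 16 test), ten
seeded iterations. All datasets share one split plan so cross-dataset
comparisons are paired per iteration.

Within an iteration, PCA is fitted on the training rows only, keeping the
smallest component count whose cumulative explained variance reaches 95 %;
test rows are projected with the training mean and loadings. Fitting PCA
per iteration on training data only is the stricter reading of the
workflow's description and prevents test-set leakage; per-iteration
provenance (which patients' rows entered PCA and training) is recorded and
asserted structurally in tests. Classifier defaults: SVM RBF C = 1
γ = scale; RF 100 trees, √p features per split, seeded; kNN k = 5
Euclidean; LR L2 C = 1. Ten-fold stratified CV on the training scores is
computed when `run_cv` is enabled and reported separately; headline metrics
always come from the held-out patients.

Metrics use cancer as the positive class. AUC is the rank (Mann–Whitney)
formulation with ties counting ½, computed from decision values (SVM) or
cancer-class probabilities (others); tests pin it to an O(n²) pairwise
oracle and to the trapezoidal ROC area. Across iterations each metric is
summarised as mean, SD (ddof 1), t-based CI (mean ± t₀.₉₇₅,₉·SD/√10) and
coefficient of variation.

The unsupervised view fits PCA on all rows without labels and reports
PC1/PC2 scores with per-group 95 % ellipses: the eigen-decomposition of the
group's 2×2 score covariance scaled by the χ²₂ 0.95 quantile. Groups with
fewer than 3 rows get no ellipse.

## Biomarker regions

Per iteration, a seeded Random Forest is fitted on the training spectra in
the original wavenumber space (not PCA scores — ranked outputs must *be*
wavenumbers) and the ten highest mean-impurity-decrease features form the
panel, ties broken toward the lower wavenumber. Panel members from all ten
iterations are binned into fixed 12.6 cm⁻¹ bins anchored at the truncation
lower edge (900 or 750 cm⁻¹; for fused data each modality block is anchored
at its own edge and regions carry their source modality). A per-wavenumber
one-way ANOVA (cancer vs control, on the same pre-processed intensities the
classifiers see) screens members at α = 0.05; occupied bins with surviving
members are reported with occurrence count and p-value range. With the
default generator the planted 1733 cm⁻¹ effect is recovered as a
significant region within half a bin width in essentially every seed.

## Group statistics

`manova_pca` pools the two groups, applies the same 95 %-variance PCA, and
tests equality of mean score vectors with Wilks' Λ via Rao's F
approximation (with two groups and one component this reduces exactly to
the one-way ANOVA F; Pillai's trace is available as an option and is an
equivalent test for two groups). A guard raises when the retained
dimensionality exhausts the within-group degrees of freedom. Null
calibration (uniform p-values) is verified by simulation in the tests.

`t_test_from_summary` defaults to Welch (the summary-only inputs cannot
justify equal variances); both variants agree on every conclusion drawn
from cohort-level summaries. `pearson_chi2` applies no continuity
correction and drops all-zero rows/columns (empty categories, e.g. an
unpopulated underweight BMI class) before computing df = (r−1)(c−1).

## Problem sizes and determinism

Everything is a pure function of the configured seeds: the generator from
`SyntheticConfig.seed`, splits and classifiers from `EvalConfig.master_seed`,
ranking from `RankingConfig.seed`. Multi-seed properties (null calibration,
fusion ordering, biomarker recovery) are evaluated over ten study seeds in
the tests; the acceptance script averages the study metrics over five seeds
and the biomarker recovery over ten, sizes chosen to keep a full
reproduction run in the minutes range on a single CPU while leaving the
Monte-Carlo error well inside the decision margins.

## Known limitations

* The generator's independence assumptions (across bands, patients and
  modalities) are simplifications; real plasma spectra have strong
  biochemical covariance, so absolute accuracies here are not forecasts for
  real cohorts.
* The atmospheric correction is a stand-in with the stated objective, not a
  reimplementation of any vendor algorithm.
* Classifier hyperparameters are fixed defaults; there is deliberately no
  hyperparameter search, nested CV or calibration analysis.
* Molecular band assignments are static annotations, not computed claims.
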