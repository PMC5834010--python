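# Methods

## The measurement

The quantity of interest is a per-slide summary of lymphocyte infiltration.
For each detected lymphocyte *i*, let *R*ᵢ be the **average** Euclidean
distance to its *N* nearest lymphocyte neighbours (*N* = 50); the local
density estimate at *i* is *ρ*ᵢ = *N*/(π*R*ᵢ²), and the slide summary is
the median of {*ρ*ᵢ}. Medians of even-length sets average the two central
order statistics. Coordinates are continuous microns, origin at the
top-left corner, y increasing downward (raster convention), so densities
are lymphocytes/µm²; reports label the column "a.u." because downstream
analyses use only the relative scale.

Conventions where the defining formula is silent:

- **Sparse slides.** With 2 ≤ n ≤ 50 lymphocytes, *N* is truncated to
  n − 1 (recorded as `k_used`); with n < 2 the summary is missing. This
  keeps the statistic defined on sparse sections while flagging the
  truncation in the output.
- **Edge effects.** No boundary correction is applied — the formula is
  used exactly as defined. Near the field border neighbours are
  systematically farther, so densities are biased downward; at reference
  conditions (λ = 2000/mm², 1 mm field, N = 50) the median summary is
  ≈ 2.12 × the true intensity rather than the ≈ 2.25 × expected on an
  infinite plane (the factor exceeds 1 because *R* averages the 50
  nearest-neighbour distances, which is smaller than the 50th distance).
  This calibration constant is pinned by simulation as a regression value;
  only proportionality to intensity matters for the analyses.
- **Coordinate duplicates.** A lymphocyte whose *R*ᵢ is exactly zero (all
  k neighbours coincident) has no finite density; it is excluded from the
  median with a logged warning rather than mapped to infinity.
- **Ties.** The k smallest distances are taken as a multiset of values, so
  exact ties do not depend on point identity or ordering.
- **Change metric.** Pre→post change is the arithmetic difference
  (post − pre); ln(post/pre) is also emitted when both are positive, since
  the parameterisation of "change" is a modelling choice. Missing
  summaries propagate to a missing change, with the record retained.

The implementation queries a `scipy.spatial.cKDTree`; tests verify
equality with an all-pairs brute-force sort to 1 × 10⁻⁹ relative
tolerance, rigid-motion invariance at the same tolerance, and exact 1/c²
covariance under coordinate scaling by c.

## Synthetic slides

The generator emulates the geometry of an H&E section, not its texture.
Each class (cancer, stromal, lymphocyte) is an independent homogeneous
Poisson process with configurable intensity (defaults 800, 600 and
500/mm² — nuclear densities of the right order for breast tumour tissue,
chosen for testability since per-slide count distributions of real
sections are not modelled here). Lymphocytes can instead follow a Thomas
cluster process (Poisson parents, Gaussian-scattered offspring, parents
simulated on a 4σ-dilated window) because real TIL infiltrates are
clustered; Poisson is the default for calibration tests. An optional
hard-core thinning (`min_separation_um`) produces non-overlapping
configurations for detector validation.

Rendering draws each nucleus as a filled rotated ellipse in optical-density
space with class-conditional parameters:

| class      | equiv. radius (µm) | elongation | haematoxylin OD | OD texture sd |
|------------|--------------------|-----------|-----------------|---------------|
| lymphocyte | 3.0 ± 0.25         | 1.0–1.15  | 1.00            | 0.02          |
| stromal    | 4.0 ± 0.4          | 2.5–3.5   | 0.70            | 0.04          |
| cancer     | 6.5 ± 0.7          | 1.1–1.5   | 0.45            | 0.10          |

on a uniform eosin-pink background (eosin OD 0.25), converted to RGB
through the standard Ruifrok–Johnston H&E stain matrix at 0.5 µm/pixel
(≈ 20× scan), plus additive 8-bit Gaussian noise (sd 2). This is the
minimal model that makes segmentation and three-class classification
non-trivially learnable: classes overlap in any single feature but are
separable jointly. It deliberately omits stain variation, out-of-focus
blur, tissue folds, overlapping chromatin texture and whole-slide scale,
so passing tests demonstrate correctness of the measurement chain, not
performance on real slides.

## Segmentation

Colour deconvolution (fixed H&E stain matrix) → Gaussian smoothing
(σ = 1 µm) → Otsu threshold (or a fixed OD) → hole filling →
distance-transform watershed with peak markers at least 4 µm apart → area
filter (8–250 µm², generous bounds around the rendered radii). All scales
are specified in microns and converted through a mandatory
`microns_per_pixel` with no default, forcing explicit calibration. Output
objects are sorted row-major by centroid, making the stage deterministic.
A constant or empty image yields an empty list, not an error. On
non-overlapping synthetic slides the detector achieves recall and
precision ≥ 0.95 with centroid errors below one nucleus radius; only
centroids feed the density statistic, so approximate masks suffice.

## Classification

Seven features per nucleus: area (µm²), eccentricity, solidity,
equivalent diameter (µm), mean and sd of haematoxylin OD under the mask,
and circularity 4πA/P² (clipped to [0, 1] against pixelation). Features
are standardised (a constant feature gets scale 1 — it carries no
information) and fed to an RBF-kernel SVM (C = 1, γ = "scale", one-vs-one
for the three classes), trained on equal per-class counts in the intended
regime (~1000 objects per class), so no class reweighting is applied. The
feature set is a replaceable design choice; any representation separating
the rendered classes would serve. Held-out accuracy on freshly generated
slides exceeds 0.95 at the default class separation; every class recall
exceeds 0.9. Standardisation constants travel with the pickled model file
(versioned format) so prediction is self-contained. All segmented objects
are classified; no QC filter is applied beforehand.

## Synthetic cohorts

One row per patient. Covariate defaults: age ~ N(50, 10²) years; grade
∈ {1, 2, 3} with probabilities (0.10, 0.45, 0.45); ER positive 60%; node
positive 45%; tumour size > 50 mm 15%; treatment arm balanced.
Pre-treatment density is log-normal (median 0.5 a.u., log-sd 0.6).
The pCR outcome is Bernoulli with

logit P(pCR) = β₀ + β_d · density + Σ βⱼ xⱼ,

with default β_d = ln 2.13 per density unit and covariate log-odds of
ln 2.80 (grade, per level), ln 0.29 (ER+), ln 0.98 (age, per year),
ln 0.65 (node+), ln 0.60 (non-bevacizumab arm), ln 1.05 (size > 50 mm) —
the adjusted effect sizes the association analyses are designed to
recover — and β₀ = −2.45, giving a marginal pCR prevalence near 20%.
Survival times are exponential (OS baseline 0.045/yr, DFS 0.07/yr) with
configurable covariate log-hazards and independent exponential censoring
(0.25/yr); OS and DFS are drawn independently, a simplification (real DFS
events precede or coincide with OS events). Post-treatment density is
pre-density times a log-normal factor from a two-component scheme: an
upward component (mean log-ratio +0.6) with probability 0.35 given
residual disease versus 0.05 given pCR, otherwise a downward component
(mean −0.7, sd 0.35) — encoding the direction of the density-increase /
residual-disease association, which is all the analysis assumes. Slide
availability flags (78% baseline; 63% of those with a matched
post-treatment slide) drive the cohort-accounting stage.

## Association analyses

- **Logistic regression** (statsmodels Newton MLE, log-likelihood
  tolerance 10⁻⁸): odds ratios exp(β) with Wald CIs exp(β ± 1.96 SE) and
  Wald p-values. Complete-case deletion per model with the per-model n
  reported. Perfect separation and constant outcomes are flagged as
  non-converged; no OR is emitted. Reference categories are the first
  listed level of each covariate (Negative ER/nodes, BEV+D FEC arm,
  ≤50 mm size); the size boundary "<51 vs >50 mm" is coded ≤50 vs >50 so
  the classes are exhaustive on integers. Density may enter raw or
  min-max rescaled (`rescale_unit_interval`, presentation only); the raw
  a.u. scale is the default and the scale in use is visible in the output.
- **Kruskal–Wallis**: tie-corrected H with a χ²(groups − 1) p-value
  (scipy backend); an all-identical input returns H = 0, p = 1 rather
  than an error.
- **Cox proportional hazards** (lifelines, Efron tie handling): fitted
  separately within ER strata because proportionality is known to fail
  across them; follow-up starts at surgery; endpoints OS (all-cause
  death) and DFS (first invasive relapse, or death without relapse).
  Zero events or non-positive times are errors.
- No multiple-testing adjustment is applied; p-values are reported raw.
- Flow percentages round half away from zero to integers.

## Validation by simulation

The clinical effect estimates themselves require the (non-public) trial
data, so the estimators are validated by parameter recovery: cohorts
simulated with the adjusted density effect (OR 2.13) as truth, 200
replicates of n = 20 000, must yield 95% CIs covering the truth in ≥ 93%
of replicates and a pooled estimate equal to the truth within Monte-Carlo
error; the Cox estimator is checked the same way (true HR 2, n = 5000,
~30% censoring). Imaging-chain validation uses 0.5–0.7 mm fields at
0.5 µm/pixel with ~150–600 nuclei per slide — large enough for stable
recall/accuracy estimates while keeping the default suite fast. These
problem sizes are the package's validation conditions and are fixed in
the tests and `scripts/acceptance.py`.

## Known limitations

- No tumour-bed masking: all detected lymphocytes count, whereas a
  pathologist would restrict to the tumour region.
- No edge correction (documented bias above); fields are small relative
  to R₅₀ at low intensities, where the bias is largest.
- The renderer's simplicity means classifier performance numbers do not
  transfer to real H&E material; the package validates the computation,
  not the histology model.
- Survival endpoints are generated independently of each other and of the
  density except through configured log-hazards.
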