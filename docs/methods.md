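# Methods

This note documents the models and procedures implemented in `pibquant`, the
defaults that define its simulated study conditions, the numerical choices
made where the design was open, and what the tests do and do not demonstrate.

## 1. Template geometry and atlas

All images live on a fixed template grid (default 64×64×48 voxels, 3 mm
isotropic). The anatomy is deliberately synthetic: a cerebral ellipsoid with
a white-matter core, a grey-matter shell partitioned by elevation band and
azimuth into 19 named cortical sectors, four subcortical nuclei (caudate,
putamen, thalamus, hippocampus) embedded inside the core, and a separate
cerebellar ellipsoid — 23 ROIs plus the cerebellar reference plus white
matter. The parcellation is defined in normalized coordinates, so a reduced
grid (32×32×24 at 6 mm) has the same topology; the reduced grid is what the
Monte-Carlo recovery experiments use, as a desk-scale choice. Geometric
fidelity is *not* a goal: the atlas exists so that masking, erosion, label
mixing under blur and reference-region statistics can be exercised with
known truth.

## 2. Ground-truth cohort model

Per-diagnosis neocortical composites are drawn from two-component Gaussian
mixtures. The MCI and AD positive components are **moment-matched** so the
mixture reproduces the target total mean/SD exactly (law of total mean and
variance), given the positive weight and negative component:

| group | weight⁺ | negative comp. | positive comp. (derived) | totals |
|---|---|---|---|---|
| control | 5/51 | N(1.26, 0.07²) | N(1.674, 0.10²) (set directly) | — |
| MCI | 0.65 | N(1.26, 0.07²) | N(1.8446, 0.2573²) | 1.64 ± 0.35 |
| AD | 0.90 | N(1.30, 0.08²) | N(1.9111, 0.2752²) | 1.85 ± 0.32 |

Composites are floored at 1.0 (a retention ratio below the reference is not
meaningful here; the floor is ~4 SD below the negative means and has no
practical effect). Regional truth: all cortical regions carry the composite
value (regional retention is near-perfectly correlated in this disease
spectrum), striatal/thalamic regions carry `1 + 0.7·(composite − 1)`, the
hippocampus is drawn from the low N(1.26, 0.07²) distribution in **all**
groups (the null hippocampal finding), white matter is fixed at 1.8
(nonspecific binding), cerebellum is exactly 1.

ApoE ε4 carriage probabilities are 10/31, 31/45 and 48/85 for
controls/MCI/AD. In MCI, carriers draw from the positive component with
weight 0.80 and the non-carrier weight is solved so the marginal positivity
stays 0.65; this produces a carrier–retention association specifically in
MCI. Genotype is recorded as missing for centre C (no genotyping there).

Cognition scores (MMSE, immediate/delayed verbal recall Z, nonverbal recall
Z) follow `score = group_mean + slope·(composite − group_mixture_mean) + ε`,
with the residual SD solved so each group SD matches its target. Slopes:
−2.34 (MCI) and −0.82 (AD) for delayed verbal recall, −1.0 for MMSE, −1.5
and −0.5 elsewhere; `scripts/calibrate_cognition.py` prints the derived
coefficients and verifies the pooled correlations (r ≈ −0.59 with delayed
recall, ≈ −0.42 with MMSE at large n). Per-test missingness reproduces the
per-test sample sizes of the study population. MMSE is rounded to integers
and clipped to [0, 30].

Follow-up exists for MCI only, with availability 64/72 and duration
N(28, 15²) months clipped to [6, 60]. Conversion to AD is an exponential
latent time with monthly hazard 0.0445 applied only to subjects whose true
composite exceeds 1.41; the hazard of true-negatives is zero, so the
negative predictive value of a (true) negative scan is 100 % by
construction. Under this censoring the implied crude converted fraction
among positives is ≈ 0.66. A single exponential hazard cannot
simultaneously match a crude fraction of ~2/3 at this censoring *and* a KM
median of 24 months (that median implies hazard ln2/24 ≈ 0.0289); the
generator prioritizes the crude fraction, and KM-median behaviour is tested
in a dedicated simulation that uses the ln2/24 hazard explicitly.

## 3. Phantom rendering

Voxel signal = dose_scale × true ratio of the enclosing label (background
0), convolved with an isotropic Gaussian PSF (FWHM per centre), with
independent zero-mean Gaussian noise of SD = noise_fraction × local blurred
signal added per frame, and axial slices outside the centre's FOV slab
zeroed. Blur uses zero ("constant") boundary padding — outside the head
there is no activity. Noise is Gaussian and signal-proportional rather than
Poisson-like: adequate for ratio statistics at these count levels and much
simpler. Frames are independent renderings of the same static ratio map;
there is no tracer kinetics, no motion, no registration error and no MRI
simulation.

Five default centre profiles (A–E) differ in PSF FWHM (5–6.5 mm), noise
fraction (0.06–0.09), dose scale (0.67–1.33, following the relative injected
activities) and frame schedule: centre A acquires six 5-min frames over
40–70 min, the others cover 40–60 min with varying run-in. PSF and noise
figures are plausible reconstructed-resolution values chosen once — no
published per-centre figures exist. Default per-centre subject allocation
follows the study's demographics table (controls absent at centre A, etc.).

Grey-matter probability maps are 0.9 inside GM labels and 0.1 outside, plus
a smooth subject-specific Gaussian random field (SD 0.05, 1.5-voxel
smoothing), clipped to [0, 1].

## 4. Mask and ROI construction

The GM mask includes a voxel iff the mean probability across the 10 maps is
≥ 0.5 (inclusive at the boundary; equivalently, summed maps ≥ half their
count). "Eroded by two voxels in all dimensions" is implemented as two
iterations of 6-connected (face-neighbour) binary erosion; the 26-connected
element is available by configuration since the stricter reading is not
uniquely determined. ROIs are the intersection of the eroded mask with the
atlas labels; empty ROIs are flagged rather than fatal (the composite
requires its three constituents). Erosion is what protects the readout from
partial-volume mixing: surviving voxels are ≥ 2 voxels from any non-GM
tissue, so at the default blur levels cross-label contamination of ROI means
is negligible (verified against an explicit-kernel convolution oracle in the
tests).

## 5. Quantification conventions

- Frame integration: a frame contributes only if fully inside [40, 60] min;
  partially overlapping frames are discarded.
- Cerebellar reference: the **median** voxel value under the (in-FOV part of
  the) eroded cerebellar mask; even counts use the mean of the two central
  order statistics. Cortical ROI values are arithmetic means — the
  outlier-robustness argument applies specifically to the low-count
  cerebellar slices.
- FOV QC: excluded iff strictly more than 25 % of cerebellar reference
  voxels lie outside the axial slab. When ≤ 25 % is truncated, the median is
  computed over the in-FOV remainder.
- The composite is the unweighted mean of the frontal, parietal and
  basal/lateral-temporal ROI means (not voxel-count-weighted).
- Scaling by the cerebellar median makes all readouts invariant to any
  global intensity factor (dose, scanner calibration), which is the point of
  the ratio design; this is asserted exactly in the tests.

## 6. Normative cutoff

`main_cluster` removes values strictly above mean + 2 SD of the current set,
iterating to a fixed point. At sample sizes where that rule cannot fire at
all — the largest standardized deviation of a sample is (n−1)/√n, which is
below 2 for n ≤ 5 — a gross outlier would be masked by its own contribution
to the SD, so the limit is then computed without the largest value. The
cutoff is `cluster_mean + 1.96 × cluster_sd` (sample SD, n−1): the upper
bound of the central 95 % normal range. A one-sided 1.645·SD limit and a
confidence interval of the mean are both rejected readings — the latter
would give ≈ 1.28 on the published moments, contradicting the published
limit of 1.41; 1.26 + 1.96 × 0.07 = 1.397 prints as 1.40, and the remaining
gap to 1.41 is attributable to rounding of the printed mean/SD. The
multiplier is configurable. Ties at the cutoff classify negative
("negative" is defined as *below* the limit). A two-component
Gaussian-mixture alternative to trimming is available
(`threshold_method="gmm"`) for sensitivity analyses.

Trimming makes the cutoff mildly conservative: on 46 calibrated-normal
controls plus 5 high contaminants the Monte-Carlo mean cutoff is ≈ 1.38
(the trimmed cluster SD is biased low by a few percent). Note the procedure
is not monotone in every input value — raising a value across the trim
limit, or raising the cluster minimum, can lower the cutoff slightly; the
tests document this.

## 7. Statistics and survival

One-way ANOVA is the classical fixed-effects decomposition. The
diagnosis × centre variance partition uses Type II sums of squares computed
by nested least-squares model comparisons (SSE differences), which remain
well-defined for the unbalanced design with empty cells; η² is each
effect's SS over the total SS. p-values are two-sided; no multiplicity
correction is applied; missing cognition values are dropped pairwise.

Kaplan-Meier estimation and the Mantel-Cox log-rank test are delegated to
lifelines (ties: events before censorings). The restricted mean survival
time is computed exactly as the step-function integral up to the largest
observed time, with the Greenwood-type estimator variance
Σ A_i² d_i / (n_i(n_i − d_i)) — note this is the SE of the *estimate*, the
quantity reported as "mean survival ± SE", not the variance of the truncated
distribution. The KM median is the first time the curve reaches ≤ 0.5 (NaN
if never). The annual conversion rate is reported both as
`1 − S_KM(12 months)` and as a person-years rate, since the derivation of a
published "≈25 %/year" figure from KM output is not unique.

## 8. Reproducibility and problem sizes

A single run seed fans out to per-stage child seeds via
`numpy.random.SeedSequence(seed, spawn_key=...)`; identical config + seed
give byte-identical cohort CSVs and JSON reports. The Monte-Carlo
experiments use, as the package's standard problem sizes: 1000 replicates
for cutoff recovery, 200 seeded replicates of full-arm rendering +
quantification on the reduced grid for calibration recovery (46
main-cluster controls, 72 MCI, 97 AD per replicate), and 500 replicates of
43-subject survival arms for the KM median check.

## 9. What passing tests show — and what they don't

Calibration recovery demonstrates that the implementation is a faithful,
nearly unbiased estimator *of its own generative model*: recovered group
means sit within ~0.003 of the configured mixtures, and positivity rates
within a fraction of a point of the mixture-implied tails. It does not
demonstrate performance on real data: the generator has no registration
error, no atrophy or atlas mismatch, no kinetic or flow effects, Gaussian
rather than Poisson noise, a stylized geometry with generous structure
sizes, and a conversion process that is exactly exponential and gated
exactly at the true cutoff. Real-data effects of exactly the kinds excluded
here (normalization failure, hippocampal partial volume, centre-specific
reconstruction artefacts) are discussed in the amyloid-PET harmonization
literature and are out of scope.
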