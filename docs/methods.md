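# Methods

This note documents the models implemented in `axispls`, the defaults and
why they were chosen, and the numerical decisions a maintainer would want
to know. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort model

The generator (`axispls.synthgen`) emulates the *statistical* structure a
preprocessed resting-state + PET cohort presents to the analysis chain; it
is not a scanner simulator.

**Grid and seeds.** Default grid 20 × 24 × 20 voxels, 170 volumes at
TR = 2 s. Three seed masks of 82 / 283 / 157 voxels fill a bilateral strip
along the y axis in anterior → middle → posterior order, preserving the
size asymmetry of real anterior/middle/posterior hippocampal ROIs that
motivates the SNR controls. Three extra-strip "network" voxel boxes carry
the anterior, posterior and shared latent courses. The anterior and
posterior boxes are forced to identical voxel counts: an asymmetric pair
biases the middle condition's mean brain score away from zero and would
contaminate the planted "neutral middle" structure.

**Signal model.** Per subject, three latent courses A(t), P(t), S(t) are
smoothed (Gaussian kernel, σ = 2 samples), z-scored Gaussian processes.
Voxel series are

    anterior seed:   baseline + f_a · (A + g·S + ε)
    middle seed:     baseline + f_m · (m_s·A + (1−m_s)·P + g·S + ε)
    posterior seed:  baseline + f_p · (P + g·S + ε)
    anterior net:    baseline + w_ant  · e_ant  · A + ε
    posterior net:   baseline + w_post · e_post · P + ε
    shared net:      baseline + w_shared · e_sh · S + ε
    background:      baseline + ε

with ε iid N(0, noise_sd²), noise_sd = 1 — the simplest model satisfying
the assumed second-order structure. The subject-specific mixture weight
m_s ~ N(0.5, 0.15) truncated to [0, 1] makes the middle seed a blend of
both networks, neutral on average. Adherence weights w ~ N(1, 0.25²) scale
each subject's network expression. Effect sizes default to
e_ant = e_post = 1.0, e_sh = 0.8, seed shared gain g = 0.5; no published
effect sizes exist for this structure (they are properties of unavailable
cohort data), so these are fixed calibration choices giving strong but not
degenerate planted signal at n of a few dozen, set once.

Region fluctuation amplitudes f_r are derived from target temporal SNRs
(292.8 / 428.6 / 590.3 — anterior < middle < posterior around a baseline of
1000 a.u.), reproducing the anterior-to-posterior SNR gradient that makes
SNR a necessary covariate. An optional `middle_course="independent"` mode
gives the middle seed its own latent course, used when the three seed
regions must be spatially separable ICA sources.

**Behaviour.** Each behaviour column (memory, D2DR) is built as
Σ ρ_k·z(w_k) + √(1 − Σρ²)·ε over z-scored adherence weights, so the
configured ρ are the population correlations with the planted weights.
Defaults couple both memory (ρ = 0.5) and D2DR (ρ = 0.4) to the *shared*
network — the generative counterpart of a memory- and receptor-related
network expressed equally along the axis. Memory trials are
Binomial(items, p_s) with p_s = clip(0.65 + 0.08·z), so task sums respect
the 32 / 16 / 24 maxima and extreme ability attains them. Missing trials
are planted completely at random, the assumption under which mean
imputation is unbiased. Binding potentials are clipped-normal,
BP ~ N(0.3, 0.1), a plausible extrastriatal D2DR range.

**What the generator does not emulate:** head-motion artefacts,
physiological noise structure, spatial autocorrelation of noise, slow
drifts, registration error, partial-volume effects, or any acquisition
physics. Passing recovery tests therefore demonstrates correctness of the
analysis chain under the assumed second-order model, not robustness to
real-data artefacts.

## Seed maps and SNR

Seed signal is the unweighted mean over ROI voxels (no weighting scheme is
assumed). Correlations are clipped to |r| ≤ 1 − 1e-7 before the Fisher
transform, because r = ±1 arises in noiseless synthetic data and atanh
would return ±∞. Zero-variance voxels yield z = 0 and a QC count rather
than NaN, so degenerate voxels never poison a downstream matrix. ROI SNR
is mean-over-time / SD-over-time of the ROI-average signal (sample SD);
constant signals give a flagged infinite-SNR record.

## PLS

**Mean-centered variant.** Condition × voxel matrix of means, centred by
its grand column mean, decomposed by SVD ("task PLS" centering). Percent
variance of LV i is s_i²/Σs². Brain scores project the *raw* rows of X
onto the voxel saliences. X columns are not z-scored in this variant
(configurable upstream by the caller; centering beyond the condition
contrast is not assumed).

**Behavioural variant.** Within each condition, X and Y columns are
z-scored across subjects (sample SD); the stacked blocks
R_c = Y_cᵀX_c/(n−1) are exactly Pearson correlations, and the SVD of the
stack yields LVs whose correlation scores are the per-condition Pearson
correlations between behaviour and brain scores. Zero-variance voxels
within a condition contribute zero correlation rather than an error
(constant background voxels are legitimate in synthetic data); a constant
*behaviour* column is an error naming the column and condition.

**Permutation schemes.** Mean-centered: condition labels are permuted
within subject across conditions (the subject is the exchangeable unit of
the condition contrast). Behavioural: Y rows are permuted across subjects
within each condition. p = (1 + #{s*_i ≥ s_i})/(1 + n_perm), so p never
returns zero; default 1000 permutations, minimum 100.

**Bootstrap and alignment.** Subjects are resampled with replacement,
preserving each subject's rows across conditions; draws with fewer than 3
distinct subjects are redrawn and counted. Bootstrap solutions must be
aligned to the reference SVD before aggregation because singular vectors
are sign- (and under near-degeneracy, rotation-) indeterminate. The
default aligns each LV by sign on the condition/behaviour salience side.
A full orthogonal-procrustes rotation is available
(`alignment="procrustes"`) but is *not* the default: on planted
three-condition cohorts the full-basis rotation absorbs genuine LV1↔LV2
rotation variability into the alignment, roughly halving the bootstrap SD
of the middle condition's mean brain score relative to its across-cohort
sampling SD and collapsing CI coverage; sign-only alignment reproduces
the across-cohort SD and restores nominal coverage. Procrustes remains
the right tool when singular values are nearly degenerate and axis mixing
would otherwise inflate salience SEs.

BSR = salience / bootstrap SE; an SE of exactly zero yields a signed
infinite BSR (flagged, excluded from cluster maps by the caller). CIs are
95% percentile intervals — for condition-mean brain scores the bootstrap
draws are retained so arbitrary condition contrasts get exact percentile
CIs rather than conservative endpoint differences; for behavioural PLS the
CIs cover the per-condition behaviour–brain-score correlations.

**Cluster extraction.** Suprathreshold voxels (|BSR| ≥ 3.3, the two-tailed
normal critical value at p = 0.001) are grouped by 26-connectivity,
positive and negative tails separately so oppositely-signed networks never
merge. Components smaller than 10 voxels are dropped. "Contiguous" and
"10 mm between clusters" are operationalised as: a surviving component
whose peak lies within 10 mm of a stronger component's peak is absorbed as
a sub-peak of that cluster (sizes summed); additional local maxima inside
a cluster at least 10 mm from every stronger listed peak are reported as
sub-peak rows without a size, the layout of standard results tables.

**Sign convention.** `orient_result` flips each LV so a chosen row of the
condition saliences (by default the first — anterior) is non-negative;
positive brain scores then denote adherence to the anterior network, the
convention assumed by the axis-group classification.

**Seed-region exclusion.** For condition contrasts the stack is restricted
to extra-seed voxels (`ConnStack.restrict`): each seed's trivial
self-correlation otherwise dominates the contrast and dilutes recovery of
the planted network pattern.

## Logan reference-tissue analysis

The simplified reference Logan: OLS of ∫₀ᵗC_t/C_t(t) on ∫₀ᵗC_ref/C_t(t)
over frames with mid-time ≥ t*, slope = DVR, BPnd = DVR − 1. The k2′
correction term is omitted — with no published regional k2′ for this use
the term is absorbed into the intercept; this is a documented limitation
that biases BPnd slightly when reference efflux is slow. Default
t* = 20 min leaves the transient well behind for k2 in the 0.1–0.2 /min
range (noiseless recovery of BP = 0.3 is within 2%, verified against an
ODE oracle in the tests). Cumulative integrals are trapezoidal at frame
mid-times with the first segment from (0, 0) — activity is assumed zero at
injection; exact for linear-through-origin activity. Frames with zero
target activity are dropped with a warning; fewer than 3 usable frames is
an error. The default 18-frame, 55-minute schedule (4×1, 6×2.5, 8×4.5 min)
is a standard short-to-long dynamic progression; the generator reports
frame *means* of the continuous curves, as a scanner does, computed by an
exponential-integrator recursion (second-order accurate, dt = 0.01 min).

## Cohort statistics

* **Composite memory:** trial sums per task → z-standardise (sample SD)
  across subjects → average → rescale to sample mean 50, SD 10. The
  transform makes mean/SD exact identities on any non-degenerate input.
* **Imputation:** missing entries take the across-subject mean of observed
  values of that variable; counts and fractions are logged; an entirely
  missing variable is an error.
* **ICV adjustment:** adjusted = raw − b·(ICV − mean ICV), b the OLS slope
  of volume on ICV; leaves adjusted volumes exactly uncorrelated with ICV
  and preserves the raw mean.
* **Residualisation:** OLS on [intercept, nuisance], residuals plus the
  original mean; rank deficiency is an error listing columns.
* **MANOVA:** Wilks' lambda with F approximation for the joint predictor
  block (statsmodels), plus per-dependent block F tests (full vs
  covariates-only). With a single dependent the Wilks F reduces exactly to
  the univariate ANCOVA block F, computed directly. Reported degrees of
  freedom follow the implemented design matrix (intercept + predictors +
  covariates); published F df under alternative design conventions may
  differ, so the result object carries its own df explicitly.
* **Classification:** by the sign pattern of aHC/mHC/pHC LV1 brain scores
  (positive = anterior network). Opposite aHC/pHC signs form the two
  axis-division groups split by the mHC sign; concordant triples form the
  all-anterior / all-posterior groups; aHC and pHC concordant with mHC
  opposed is excluded. An exact zero score is surfaced as an error rather
  than silently assigned (a measure-zero event on continuous data); an
  optional tolerance breaks ties toward the region's mean sign.
* **Group tests:** pooled-variance two-sample t with one-tailed p in the
  stated direction (Welch is not assumed).

## Problem sizes in the test suite

Recovery and calibration experiments run at desk scale, chosen as the
smallest sizes at which the checked statistical property is expected to
hold with margin: permutation type-I calibration uses 500 pure-noise
replicates (20 subjects × 3 conditions × 50 voxels, 200 permutations);
bootstrap CI coverage uses 200 replicates of a planted two-condition
contrast (50 subjects, 20 voxels, 300 bootstraps); planted-contrast
recovery runs the full image pipeline at the default grid with 40
subjects; the end-to-end behavioural pipeline check uses 30 seeded
replicate cohorts on a reduced 12 × 16 × 12 grid. Stochastic checks use
fixed seeds and tolerances derived from exact binomial bands.

## Known limitations

* The ICA parcellation whitens spatially without removing the voxel mean,
  which keeps signal-free voxels at exactly zero weight and separates
  unequal-size sources cleanly; perfectly symmetric equal-size disjoint
  sources are a measure-zero degenerate configuration where fixed-point
  ICA can stall at the 45° mixture.
* The middle-seed mixture makes the three seed regions non-separable as
  ICA sources when the shared course is active; ROI-recovery analyses use
  the independent-course generator mode.
* Behavioural-PLS brain scores are computed on within-condition z-scored
  maps (matching the correlation-block decomposition), so their scale is
  not comparable to mean-centered brain scores.
* No voxelwise BPnd maps, no SRTM fitting for estimation (the kinetic
  model appears only in the generator), no split-half PLS, no
  structural-equation modelling of memory.
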