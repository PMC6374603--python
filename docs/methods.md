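# Methods

`mindtrack` implements a neural-decoding analysis of avoidant grief: it
learns subject-specific spatial patterns for two mental processes —
deceased-related selective attention (d-SA) and deceased-related mental
representation (d-MR) — from labelled task fMRI, tracks their expression
TR by TR during neutral sustained-attention (SART) tasks, and tests
whether avoidance moderates the interaction between the two expressions in
predicting self-reported thoughts of loss.  Because no imaging data
accompany the design, a first-class synthetic-data module generates every
input with known ground truth; all statistical claims the package makes
are verified against that truth.

## Task designs (`designgen`)

Four paradigms are generated deterministically given a seed:

* **Grief Stroop** (d-SA training): 4 runs × 4 word-condition blocks
  (deceased, living, congruent, incongruent) × 15 words; 1.5 s words,
  jittered ITI averaging 2 s, 10 s fixations between blocks — 60 trials
  per condition.  The jitter distribution is uniform on [1, 3] s (bounds
  are a package choice; only the 2 s mean is prescribed by the design).
* **Person representation** (d-MR training): person blocks (deceased /
  living control / demographic control) of two 7.5 s pictures, a 3 × 5 s
  story, and a 15 s "imagine being together" instruction, each modality
  followed by a 0.5 s fixation — 46.5 s of stimulus + fixation per block —
  then 1–5 valence and arousal probes.  Three blocks per person condition
  (the block count is a package choice; it is the smallest count that lets
  the three stories alternate across blocks with each story appearing
  once per condition).
* **SART**: go/no-go digits (1.5 s, mean-2 s jitter), 11% no-go ("3"),
  no two consecutive no-go trials (placement rule is a package choice).
  The continuous variant spans 8 min; the probed variant has 16 blocks of
  25–35 s, each followed by three yes/no thought probes in fixed order
  (deceased, living, self), 3 s per probe.  A block's duration is the
  drawn span; time after the last whole trial is fixation.
* TR bookkeeping is 1-based with half-open intervals (TR *i* covers
  [(i−1)·TR, i·TR)).  The TR defaults to 2 s and is configurable; all
  window rules are expressed in TR units so this choice stays isolated.

## Synthetic BOLD and the generative cohort (`boldsim`)

Ground truth consists of two spatially disjoint weight maps — smoothed
Gaussian random fields on separate slabs of the volume, standing in for
the basal-ganglia-like d-MR system and the frontotemporoparietal d-SA
system — demeaned within their support (so a region-mean signal carries no
pattern information) and normalized to unit RMS.  Voxel signal is

    bold(v,t) = snr · [w_dsa(v)·s_sa(t) + w_dmr(v)·s_mr(t)]
                + drift + motion-coupled nuisance + AR(1) noise,

with unit-variance HRF-convolved states, so `snr` is the signal amplitude
at a typical pattern voxel in noise-s.d. units.  The HRF is the canonical
double gamma (peak 6 s, undershoot 16 s, ratio 1/6, unit peak).  Latent
states per task: on the Stroop, the d-SA state fires on deceased words
with amplitude equal to the trial's latent attention capture, which also
drives that trial's RT excess (RT = condition base + 0.08 s/s.d. coupling
+ noise, floored at 0.2 s); on the representation task the d-MR state is a
boxcar over deceased picture and story events; on the SARTs both states
are smooth AR(1) fluctuations (φ = 0.85 per TR).

Thought-probe responses follow a full-factorial random-intercept logistic
model on within-subject-standardized block-mean states and cohort-
standardized avoidance:

    logit P(thought) = b0 + b_mr·mr + b_sa·sa + b_av·av + b_mrsa·mr·sa
                       + b_mrav·mr·av + b_saav·sa·av + b_three·mr·sa·av

with default coefficients taken from the reported per-s.d. factorial
estimates (b_mr = 0.33, b_sa = 0.72, b_av = 1.0, b_mrsa = 2.21,
b_mrav = −0.25, b_saav = 1.11, b_three = −2.37), a 0.5-s.d. random
intercept, and b0 = −1.5355 calibrated by Monte Carlo so the *marginal*
loss-thought rate on error-free blocks is 85/275 ≈ 31% (the nonlinear
interactions raise the marginal rate above expit(b0), so b0 must sit below
logit(0.31)).  Blocks are flagged as error blocks with probability
1 − 275/432 ≈ 0.36, matching 275 error-free blocks in a 27-subject cohort.
Clinical covariates (IES-A avoidance, ICG, CES-D, age, months since loss
∈ [3, 14], loss type, medication) are drawn to match the reported cohort
moments.  `simulate_block_table` provides the same generative block model
without BOLD for fast statistical calibration.

One deliberate asymmetry: the default coefficient set implies high-group
and low-group d-MR × d-SA slopes of b_mrsa + b_three·E[av|group] ≈ +0.3
and +4.1 under Gaussian avoidance — i.e. the reported subgroup estimates
(−1.04 / +0.76) are not jointly consistent with the reported factorial
coefficients under any Gaussian-avoidance generative model.  Checks of the
subgroup *sign pattern* therefore use a moderation-dominant variant
(two-way interactions zeroed, b_three = −2.37), for which the implied
subgroup slopes are ∓1.9.

## Feature selection (`featselect`)

First-level GLMs use HRF-convolved condition boxcars, parametric
modulators mean-centered within condition *before* convolution, six motion
confounds, Legendre drifts and an intercept, with optional AR(1)
prewhitening (pooled lag-1 estimate; default on).  The d-SA contrast is
(deceased × RT) − (congruent × RT) with on/off regressors controlling
semantic processing; runs are combined by fixed effects.  The d-MR
analysis contrasts deceased vs the mean of both controls separately for
pictures and stories, with block-level valence/arousal ratings entering as
HRF-convolved parametric nuisance regressors (the level at which these
covariates enter is a package choice), and combines the two group maps by
a minimum-statistic conjunction.  The think modality carries no label and
enters only as a nuisance regressor.

The group model is an inverse-variance-weighted one-sample test with a
DerSimonian–Laird method-of-moments between-subject variance — the
intent of a hierarchical mixed-effects group analysis without
re-implementing FLAME.  Cluster correction thresholds the group z map
(one-sided voxel p; d-SA 0.01, d-MR 0.001), groups voxels by
26-connectivity, and retains clusters larger than the (1 − α) quantile of
the maximum-cluster-size distribution under subject sign flipping
(cluster α: d-SA 0.05, d-MR 0.1).  This permutation null is self-contained
and valid at desk-scale volumes where smoothness-based corrections are
not.  Note that with integer cluster sizes the test is conservative
(FWER ≤ α); its calibration is checked at voxel-p = 0.05, where null
clusters are large enough for the discrete null to resolve the 5% tail.

## Pattern training (`mvpa`)

Per-event samples are averages of per-voxel z-scored BOLD over the
hemodynamically delayed window [onset + 4 TR, onset + 4 TR + duration),
mirroring the offset used at decoding time.  The d-MR classifier is an
L2 logistic regression (deceased vs both controls, picture and story
events pooled, think excluded) with leave-one-fold-out CV over block
triplets; the d-SA regressor is a ridge regression of deceased-word RT
with leave-one-run-out CV.  Regularization is chosen by inner CV (AUC for
the classifier, MSE for the regressor) over wide grids — with far more
voxels than events the inner CV typically selects strong regularization.
The final decoding pattern W averages the fold weight vectors; reported
performance is the mean out-of-fold AUC (midrank ties), or the mean
per-fold out-of-fold Pearson r (per-fold correlation avoids the negative
fold-intercept bias pooled out-of-fold correlations exhibit under the
null).  Significance uses within-run label permutation,
p = (1 + #{null ≥ observed})/(1 + n_perm).

Each model also stores the forward-model activation pattern
A = cov(X)·W.  Decoding always uses W, but comparisons with generative
truth use A: regularized backward-model weights provably rotate away from
the generative pattern as SNR grows (the fit suppresses the high-variance
signal direction), while the activation pattern is the interpretable
spatial image of the decoded process.

## Pattern expression (`decode`)

SART series are cleaned by per-voxel residualization on the six motion
parameters, then z-scored per voxel (voxels fully explained by confounds
become all-zero).  Expression is the masked dot product
expression(t) = Σ_v w_v·bold_v(t).  Block averages run from 4 TRs after
the previous probe period's end through 2 TRs into the block's own probe
period (block 1 anchored 4 TRs after the first trial's onset); the
whole-task average runs from task start + 4 TRs to task end + 2 TRs.
Pooled block-average expressions are winsorized at Tukey fences
(quartiles by linear interpolation, fences Q1/Q3 ∓/± 1.5·IQR), censoring
outliers to the nearest observed in-fence value — the fence reading is the
only one consistent with single-digit outlier counts.  Error blocks are
flagged here but excluded only at the inference stage.

## Inference (`inference`)

The central model is a random-intercept logistic regression of the block
thought-probe response on the full factorial of d-MR expression, d-SA
expression and avoidance, all z-scored across the pooled analysis table
(so coefficients and ORs are per predictor s.d.).  The marginal likelihood
integrates the random intercept by 40-node Gauss–Hermite quadrature with
an analytic gradient (BFGS), Wald standard errors from the numerical
Hessian, and a convergence flag rather than a silent failure.  The fit
matches `lme4::glmer` to ~1e−3 on coefficients and standard errors (frozen
as a unit test with an Rscript oracle).  Supporting analyses: a
covariate-adjusted refit (age, loss type, months since loss, CES-D), a
median-split pair of subgroup models (at-median subjects go to the high
group; terms mr, sa, mr·sa), a specificity control replacing each
expression by mask-mean BOLD over identical windows, a subject-level OLS
of post-SART reports on mean expressions and avoidance with squared
semi-partial correlations (ΔR² adding the predictor last), and Pearson
correlations of the per-subject loss-thought rate (over error-free blocks)
with clinical variables.

## Problem sizes and what the tests show

Calibration and recovery checks run at desk scale: FWER over 500 null
group datasets (12×12×8 voxels, 10 subjects, 200 sign flips), permutation-p
uniformity over 200 null datasets, type-I error of the three-way Wald test
over 200 null cohorts (27 subjects × 16 blocks), coefficient recovery over
50 cohorts of 200 subjects × 16 blocks, and spatial-pattern recovery on
20×20×12 volumes at SNR 2 (the "high-SNR" regime; the real data's SNR is
unknown and is an explicit simulator parameter).  The shared integration
cohort uses 10 subjects at 16×16×10, SNR 2.

The simulator emulates the statistical structure the pipeline assumes —
linear pattern embedding, AR(1) noise, drift, motion coupling, a factorial
response model — not physiology: no balloon dynamics, susceptibility
artifacts, slice timing, spatially correlated noise, or nonstationary
states.  Passing tests show the pipeline recovers what it models; they do
not certify performance on real acquisitions.

## Known limitations

* Wald inference on the three-way term is mildly liberal at 27 subjects
  (measured type-I ≈ 0.05–0.07); profile-likelihood or parametric-bootstrap
  intervals would tighten this.
* The discrete max-cluster-size null makes cluster correction conservative
  at stringent voxel thresholds on small volumes.
* Per-event pattern samples use window averaging; beta-series estimation
  is a reasonable alternative the package does not implement.
* The decoded three-way estimate attenuates relative to the generative
  coefficient (measurement error in the expression proxies); the package
  reports the decoded-scale estimate and makes no deattenuation
  correction.
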