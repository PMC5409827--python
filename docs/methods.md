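# Methods

This note documents the models, defaults, numerical choices and known
limitations of the package. All empirical statements below are properties
the test suite or `scripts/acceptance.py` computes.

## Pupil preprocessing

Cleaning follows a fixed order: (i) linear interpolation across blinks with
a 150 ms margin on each side (overlapping windows merged; edge blinks
clamped flat); (ii) third-order Butterworth band-pass, 0.01–6 Hz, applied
zero-phase (forward–backward). Zero-phase filtering is a package choice —
it keeps TPR timing unlagged — and is exposed via the `zero_phase` flag;
(iii) estimation of the stereotyped pupil responses to blinks and saccades
by joint least-squares FIR deconvolution over a 6 s post-event window,
followed by removal via multiple regression of the event sticks convolved
with the estimated responses (event types with fewer than 5 events are
skipped); (iv) conversion to percent signal change around the block mean.
The block mean is taken from the interpolated, pre-band-pass trace, since
the band-passed trace is mean-free; this ordering subtlety is a package
choice.

A trace must span at least three time constants of the 0.01 Hz corner
(~48 s) or the band-pass refuses to run: shorter traces are dominated by
filter edge transients.

## TPR and the pupil GLM

TPR = mean percent modulation in [choice − 1 s, choice + 1.5 s] minus the
mean in [cue − 0.5 s, cue]. Because the peripheral pupil plant low-pass
filters its input, RT mechanically inflates TPR; `residualize` removes RT
by OLS, with the covariate centered so the mean TPR level is preserved and
binned SDT metrics stay on the original scale. Binning is 40/20/40
(low/mid/high; low and high are the analysis bins) or k equal quantiles
(k ≤ 5), ties broken by stable trial order.

The GLM cuts epochs from cue − 1 s to cue + 5 s, baseline-corrects them by
the 0.5 s pre-cue mean (the same window as the TPR baseline), and
concatenates them. Three regressors per trial — a cue stick, a choice
stick placed 0.24 s before the button press (the lead of phasic locus
coeruleus activity over the overt response; config-overridable), and a
cue→choice boxcar whose height is 1/n_samples so all three pre-convolution
columns sum to one — are convolved with the canonical pupil IRF
h(t) = (t/t_max)^w exp(−w(t/t_max−1)), normalized to peak 1 at t_max.
Defaults w = 10.1, t_max = 0.93 s, from the canonical-IRF literature; both
are exposed. Epoch-based fitting is slightly approximate whenever
responses outlast the epoch; `build_design_session` provides the exact
continuous-session forward model, under which noiseless generator traces
are identified to machine precision.

## Signal-detection analyses

d′ = z(H) − z(F), criterion = −(z(H)+z(F))/2. Degenerate rates (0 or 1)
are corrected by the log-linear rule (add 0.5 to the cell, 1 to the
denominator); the correction is applied only when needed so that exact
textbook examples hold. Per-bin fractions of 'yes' are computed on
stimulus-balanced subsamples: all four TPR × stimulus cells are subsampled
without replacement to the smallest cell count, 1000 times, and averaged.
The preferred choice (for the non-preferred-fraction variant) is the
overall majority choice; an exact 50/50 tie counts as preferring 'yes'.

Sequential polynomial regression models a per-bin metric on orthogonalized
polynomial bases (order 0–2) of the bin-mean TPR (bin index optional),
with subject intercepts (repeated-measures form); each added order is
tested against the previous by a nested-model F-test at α = 0.05, and the
selected order is the highest significant step. Testing continues past a
non-significant linear step so that a pure inverted-U (no linear
component) is still detected as quadratic.

The paired permutation test flips the sign of each paired difference; for
n pairs with 2^n ≤ n_perm all sign patterns are enumerated exactly, making
small-n p-values deterministic. Two-sided by default.

## Drift-diffusion model

Stimulus coding: dy = (v·s + dc)dt + c dW from y0 = z·a, absorbing at 0
('no') and a ('yes'); RT = first-passage time + t0. The noise scale is
fixed at c = 1 (only ratios to c are identifiable). Across-trial drift
variability sv draws each trial's drift from N(v·s + dc, sv).

*Simulator.* Euler–Maruyama at dt = 1e−4 (default) with the
Broadie–Glasserman–Kou continuity correction: each boundary is moved
inward by 0.5826·c·√dt to compensate for crossings missed between discrete
steps. Without the correction, simulated choice fractions and RT
distributions are measurably biased at dt = 1e−4; with it, the KS distance
to the analytic distribution stays below 0.01 at n = 10⁵ across a grid of
12 parameter regimes (tested).

*Likelihood.* The exact two-boundary first-passage density is evaluated by
the standard series expansion, switching between the small-time and
large-time forms per evaluation point by the usual truncation-error bound
(absolute tolerance 1e−8). The drift-free series factor is computed once
per likelihood call and reused across the 20-node Gauss–Hermite quadrature
that marginalizes sv. Densities are floored at 1e−12 inside the
log-likelihood (this also handles rt ≤ t0).

*Fitting.* Per-subject maximum likelihood, not hierarchical Bayes: the
synthetic-data setting provides ample per-subject trials, so the shrinkage
machinery that motivates hierarchical fitting is unnecessary, and model
comparison uses AIC/BIC rather than DIC. Parameters are optimized in
transformed space (log a, logit z, t0 as a logit fraction of the minimum
RT, log sv) by multi-start adaptive Nelder–Mead (default 5 starts; the
first start is moment-informed, the rest are perturbations) followed by a
polish run. By default {a, t0, v, z, dc} are free per condition and sv is
shared; the reduced model for comparison moves dc to the shared set. No
lapse mixture is included by default.

*Bias dissociation.* `match_z_to_choice_fraction` root-solves the starting
point whose overall P('yes') matches a given drift-criterion bias;
`mode_shift_diagnostic` compares analytic RT-distribution modes. The dc
bias leaves modes nearly in place while the matched z bias shifts them
several-fold more (tested at >3×).

*Regression DDM.* The per-trial drift β0 + β1·S + β2·M + β3·C enters the
likelihood directly; M and C are z-scored; a, z, t0 are fitted but shared
across trials; sv is fixed at 0 in this variant.

## fMRI pattern statistics

Scalar responses: mean over 2–12 s from cue minus the −2–2 s baseline,
then RT-residualized. The orientation/choice voxel contrast uses the Welch
two-sample form t = (x̄₁ − x̄₂)/√(sem₁² + sem₂²); the printed formula in
some descriptions of this statistic is typographically ambiguous and the
Welch reading is the default (the literal difference-of-ratios reading is
not implemented). Voxel selection takes the 50 most positive plus 50 most
negative t-values, ties broken by voxel index. Template scores are Pearson
correlations of the held-out trial with the difference-of-means template
over the selected voxels; selection and template are recomputed inside
every leave-one-out fold, and a permutation-based leakage test verifies
chance-level indices when labels are shuffled. Searchlight decoding uses a
linear SVM (C = 1) with leave-one-trial-out accuracy ("precision score" in
some usage, but compared against a 0.5 chance level, which is accuracy);
spheres use strict-interior membership and need ≥3 voxels. ROC predictive
indices are Mann–Whitney AUCs computed within each level of the balancing
variable and averaged. Combined ROI signals are regression-weighted sums
(linear against TPR for brainstem, logistic against choice for cortex),
z-scored. TPR–brainstem correlations remove the fourth-ventricle nuisance
from ROI responses and stimulus identity from both sides first; partial
correlations additionally residualize ROI and TPR on all other ROIs (the
residual-correlation and precision-matrix routes agree to 1e−10, tested).
Probability-threshold ROI masks keep exactly the 12 highest-probability
voxels and weight the ROI time series by those probabilities.

## Synthetic data

The generator instantiates the study conditions: blocks of 40 trials with
exactly half signal-present, ITIs uniform on 4–12 s, a 2 s pre-cue
baseline, a 3.5 s response deadline, CW/CCW grating orientation
alternating by block. A binary latent arousal state (balanced within
block) sets both the trial's drift criterion (defaults −0.30 low / −0.05
high, with a = 1.4, z = 0.5, v = 0.7, t0 = 0.4, sv = 0.2 shared) and the
sustained pupil gain (0.5 vs 1.5), creating the arousal–bias coupling the
pipeline must detect. Pupil traces are the GLM forward model (betas 1, 1,
2 percent-modulation units) plus white noise (sd 1%), an AR(1) drift
(ρ = 0.99, innovation sd 0.2%) to stress the band-pass, 100–300 ms blink
dropouts at 6/min with a small recovery dilation (to exercise the 150 ms
interpolation margins and deconvolution), around a 1000 a.u. mean level.
Default sample rate 50 Hz (1000 Hz supported). Voxel-pattern amplitudes
(orientation 0.07, choice 0.03, in noise-sd units) are calibrated so the
predictive indices land in the empirically observed range (orientation
~0.63, as reported for an example subject in this paradigm; choice
~0.55–0.6). ROI responses mix a shared latent factor, a TPR-coupled
ROI-specific component, fourth-ventricle leakage and noise.

The Quest staircase maintains a grid posterior over the log10 Weibull
threshold (prior sd 0.5 log-units, assumed slope β = 3.5, lapse 0.01,
guess rate 0.5 for 2IFC), places each trial at the posterior-mean
threshold shifted to the 75%-correct point, and returns the contrast at
which the assumed psychometric predicts 75%. The exact prior/β settings of
the original staircase are not published, so the check is a convergence
property (threshold recovery, target accuracy) rather than a replication.

What the generator does *not* emulate: measurement nonlinearities and gaze
artifacts in pupillometry beyond blinks; spatial autocorrelation,
physiological noise structure and hemodynamic dynamics in the voxel
patterns (patterns are i.i.d. Gaussian around their condition means); any
raw EPI/volume-level structure. Passing tests therefore certify the
correctness and calibration of the *analysis code* under the assumed
statistical structure, not robustness to real-data artifacts outside that
structure.

## Problem sizes

Recovery studies in the test suite use sizes chosen to keep the full suite
desk-scale while leaving comfortable statistical margins: simulator–density
agreement at n = 10⁵ trials per parameter set; drift-criterion recovery
over 8 replicates of 2 × 1500 trials; pupil-GLM recovery over 20 simulated
subjects (200 blocks); regression-DDM recovery over 3 replicates of 1500
trials; ROC chance calibration over 200 simulated datasets; staircase
calibration over 100 runs.

## Known limitations

- Per-subject ML fits need both choice types in every condition; extremely
  biased small samples will be rejected rather than fitted.
- sv is weakly identified at moderate trial counts (its estimate is noisy
  even when dc/a/v/t0/z recover well); it is shared across conditions for
  this reason.
- The epoch-based pupil GLM is approximate when responses outlast the
  epoch window (see above).
- The searchlight is O(centers × trials² × SVM); it is meant for ROI-scale
  grids, not whole-brain volumes, in this implementation.
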