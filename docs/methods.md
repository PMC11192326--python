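# Methods

`earlyerp` implements a complete, testable replication surface for a
two-experiment ERP analysis of extremely early (~40 ms) emotional
discrimination in visual cortex: synthetic 64-channel EEG with planted
components, the preprocessing chain, a bespoke occurrence criterion for
the early negative deflection (N40), meta-average peak/window-of-interest
definition, spatial-PCA quantification, and a frequentist/Bayesian paired
contrast strategy with a mixed-model covariate decomposition of the
peak-to-peak effect.

## The synthetic world

Real data for the original study exist but are not required: every stage
is validated against a generative model whose ground truth is known.

**Designs.** Design 1: 20 spider and 20 wheel silhouettes, 10
presentations each, at five screen locations (fixation + four quadrants)
— 200 trials per category x location (2000 total), 150 ms stimulus,
fixed 850 ms ITI, eight blocks. Design 2: fixation only, 500 trials per
category, ITI jittered over {750, 800, 850, 900, 950} ms (mean 850 ms),
four blocks. Per block, 1–5 fixation-dot-change task trials are planted
(scaled-down plans keep the ~1–2% task-trial rate instead of the absolute
count). Presentation order is a seeded permutation.

**Signal model.** Each stimulus adds two deflections with Gaussian time
course and spherical-Gaussian scalp topography:

| component | peak (design 1 / 2) | FWHM | amplitude | topography center |
|---|---|---|---|---|
| N40 (negative) | 39 ms / 45 ms | 20 ms | 3.5 uV | Oz (contralateral PO7/PO8 for peripheral) |
| P80 / P100 (positive) | 80–101 ms by location / 105 ms | 30 / 36 ms | 4.0 uV | POz (contralateral for peripheral) |

Peripheral responses are scaled to 30% of foveal amplitude (peripheral
under-representation in thalamus/V1). Spider trials receive an extra
peak-to-peak separation `category_effect_ptp` (default 1.2 uV) split
50/50 between the two deflections; each participant's effect deviates by
N(0, `participant_effect_sd` = 1.0 uV), and overall evoked amplitude
varies by a ~15% multiplicative participant factor.

**Background.** White noise (8 uV), 1/f-shaped noise (4 uV), ongoing
10 Hz alpha with a random phase per trial segment (3 uV, posterior-
weighted) — synthesized in the frequency domain with analytic
normalization — plus a common-mode 0.2 Hz drift recorded identically on
the nose reference (removed exactly by re-referencing), stereotyped
blinks (Poisson, 8/min, 150 uV on the vertical EOG, frontally weighted
on the scalp), and an 8 ms trigger-to-screen lag.

**Anticipatory baseline alpha.** With a strictly periodic stimulus train
(design 1), each baseline carries one full cycle of a 2 uV, 10 Hz
anticipatory alpha burst, phase-locked across trials and desynchronizing
at stimulus onset. This is the model's rendering of the alpha
phase-locking risk that motivated the jittered ITI in design 2 (where the
burst phase is randomized and averages out). Its role is load-bearing:
it dominates the baseline SD of averaged waveforms (~1.3 uV on posterior
channels), so the occurrence criterion's threshold (1.5 x baseline SD
~ 1.9 uV) sits between the 30%-amplitude peripheral response (~1.1 uV)
and the foveal N40 (3.5 uV). A post-stimulus phase-locked alpha was tried
first and rejected: an oscillation inside the component windows biases
meta-average peak latencies, whereas a burst confined to the baseline is
zero-mean over the baseline (no baseline-correction shift) and leaves the
search windows clean.

**What a green test does not establish.** The generator has no head-model
forward projection, no eye movements beyond stereotyped blinks, no
heavy-tailed or non-stationary noise, no per-channel impedance
differences, and components with exactly Gaussian morphology. Recovery
results certify the pipeline's internal consistency on this world, not
performance on arbitrary real recordings.

**Calibration of the planted effect.** The design target is a population
effect size of d ~ 0.75 for the fixation peak-to-peak contrast at n = 36
(the replicated study's printed value). Factor-score measurement noise at
the full design's trial counts contributes ~1.2 uV-equivalent SD —
dominated by the spatially coherent alpha, which is anti-correlated
between the two component windows (~41 ms ~ half an alpha period apart)
and therefore does not cancel in the peak-to-peak difference. The
defaults (effect 1.2 uV, participant SD 1.0 uV) give
d = 1.2 / sqrt(1.0^2 + 1.2^2) ~ 0.75 including that noise.
`SimTruth.true_effect_size_d` reports the noise-free ratio (1.2), an
upper bound.

**Variance-preserving scaling.** Tests and recovery suites simulate fewer
trials with the stochastic background scaled by sqrt(n'/N). For Gaussian
stationary background this leaves the sampling law of per-condition
averages exactly unchanged; deterministic content (evoked templates,
phase-locked burst) is never scaled. The detection suite additionally
scales participants, preserving the across-participant grand-average law
(participant-level amplitude heterogeneity then averages over fewer
draws — a second-order deviation). Blinks are not scaled; they are
handled by removal/rejection, not averaging.

## Preprocessing

Offline re-reference to the nose channel; zero-phase (forward-and-
reverse) Butterworth band-pass 0.01–30 Hz, two poles per band edge,
applied to continuous data only (a high-pass applied to 300 ms epochs
would distort small early deflections). Reflection padding is capped at
2 s: ample for the 30 Hz edge, while the 0.01 Hz pole's transient is
irrelevant here because sub-0.1 Hz content is removed by re-referencing
and absorbed by baseline correction. Trigger marks are shifted forward by
the measured lag (8 ms -> 4 samples at 512 Hz).

Epochs use 154 samples on [-100, +200) ms at 512 Hz (0.300 s x 512 =
153.6, rounded up; nominal timestamps t_k = -100 + 1000k/512, which sit
0.39 ms before the true sample times — below half a sample and
irrelevant at the stated tolerances). Baseline correction subtracts the
mean of t < 0 samples per trial and channel; it is idempotent and is
re-applied after blink removal.

Trial rejection: (i) dot-change trials and their immediate successors;
(ii) any scalp sample beyond +/-100 uV; (iii) any channel whose per-trial
range (max - min) falls outside that channel's across-trial mean +/- 3.5
SD of ranges (per-channel by default; a pooled variant is available).
The SD rule is applied once, without iterative re-computation;
zero-variance channels cannot violate it. Participants are excluded when
any condition retains fewer than 150 (design 1) or 400 (design 2) trials;
scaled-down runs scale the minimum proportionally.

Blink removal offers two backends: FastICA (scikit-learn) with components
zeroed when their time course correlates |r| > 0.7 with the vertical EOG,
and per-channel least-squares regression on the EOG derivations. The
pipeline default is regression: it is exact for the simulator's
stereotyped blink model, deterministic, and fast; ICA internals are not
part of this package's contribution.

## Component machinery

**Occurrence criterion.** On each condition's averaged waveform, a
posterior channel qualifies when it has >= 2 consecutive samples within
30–60 ms whose magnitude exceeds 1.5 x the SD of that channel's own
baseline samples (either polarity by default; a polarity-restricted mode
exists). The component is present when >= 2 qualifying channels are
mutually adjacent (neighbor graph: unit-sphere chord distance < 0.45,
mean degree ~6). Qualifying channels are not required to overlap in time
(configurable). Baseline SD is computed on the averaged waveform, not on
single trials: the criterion compares averaged activity against the
average's own baseline variability.

**Peaks and windows.** Peak latency is defined on a meta-average across
a parietal/occipital electrode set — bilateral for fixation, restricted
to the hemisphere contralateral to the stimulated hemifield for
peripheral locations — and across both categories, so a single window
serves both conditions (no condition circularity). The window of interest
is peak +/- 3 ms for the negative component and +/- 6 ms for positive
components; these half-widths reproduce every printed peak->window pair.
Ties in peak finding resolve to the earlier latency. Amplitudes are
window means per participant x condition x channel; peak-to-peak is the
element-wise positive-minus-negative difference, which cancels constant
offsets and is insensitive to baseline/filter settings.

## Spatial PCA

Electrodes are variables, participant x condition cells are cases. The
channel correlation matrix (default; covariance available — the original
software's default association is not stated) is eigen-decomposed; the
retained count comes from the scree elbow, operationalized as the index
maximizing the second difference (acceleration) of the eigenvalue curve,
with a manual override for replication runs. Retained loadings are
varimax-rotated with Kaiser normalization; scores use the regression
(Thurstone) method. Sign indeterminacy is resolved by flipping each
factor so its largest-magnitude loading is positive, which keeps scores
oriented like the underlying amplitudes — necessary for one-tailed
contrasts. The analysis factor is the one with maximal mean |rotated
loading| over the posterior (laterality-filtered) channels; ties go to
the factor with larger explained variance.

## Statistics

**Double contrast.** One-tailed paired t (direction: spider > wheel on
the amplitude scale; for the negative component that means "less", i.e.
more negative), Cohen's d = mean(diff)/SD(diff) (so d = t/sqrt(n)), and a
one-sided JZS Bayes factor: Cauchy(0, 0.707) prior on the standardized
effect truncated to the hypothesized sign and renormalized,

    BF10 = Int f_nct(t; n-1, delta sqrt(n)) 2 Cauchy(delta; 0, r) ddelta
           / f_t(t; n-1),   delta > 0,

by adaptive quadrature split at the likelihood peak (relative error well
below 1e-4; cross-checked against a dense-grid oracle and, at t = 0,
against an established two-sided implementation). The five
positive-component location contrasts in design 1 share a Bonferroni
alpha of 0.05/5 = 0.01. If x and y are identical the contrast returns
t = 0, p = 0.5, d = 0 rather than failing on zero variance.

**Peak-to-peak decomposition.** Whether the condition effect on
peak-to-peak scores survives adjustment for the two single-component
amplitudes is assessed with a linear mixed model: fixed effects for
condition (effect-coded) and both covariates, a per-participant random
intercept, REML estimation (closed-form per-participant blocks via
Woodbury), Wald F with numerator df 1 and a Satterthwaite denominator
df: df = 2 g^2 / (grad g' A grad g) with g the contrast variance as a
function of the two variance components and A the inverse observed REML
information (central finite differences). The original analysis's exact
repeated-measures ANCOVA machinery is not described beyond its fractional
denominator df, so the mixed model is the documented replication surface;
its original F values are data-dependent and are not acceptance targets.
Calibration is verified by simulation: under the null the adjusted
condition test rejects at 5% +/- 2% over 1000 runs.

## Numerical choices and degenerate inputs

- Filter: scipy `butter(2, [0.01, 30], 'bandpass')` (two poles per edge,
  the FieldTrip order convention) + `sosfiltfilt`. The two-pass magnitude
  at 50 Hz is |H|^2 = 0.1065 — the filter test asserts the transfer-
  function value, not a rounder figure.
- Quadrature: `scipy.integrate.quad` per segment, epsrel 1e-8.
- Scree rule on fewer than 3 eigenvalues raises; `k` can be forced.
- Correlation-association sPCA refuses zero-variance channels; the
  covariance path accepts them.
- Zero planted effect makes `SimTruth` report a zero peak-to-peak
  difference and d = 0; zero participant SD with a positive effect
  reports d = inf.
- Mixed-model variance components are optimized on the log scale
  (Nelder-Mead); a collinearity guard (condition number > 1e8) rejects
  degenerate covariate sets.

## Known limitations

- The idealized spherical montage is a synthetic geometry; absolute
  inter-electrode distances differ from a digitized cap, so the default
  adjacency radius (0.45) is calibrated to this montage.
- The regression blink backend removes any activity linearly shared with
  the EOG, which on real data can include genuine frontal EEG.
- Satterthwaite df from numeric information can be unstable when the
  random-intercept variance estimate hits zero; the F statistic itself is
  unaffected.
- Realized contrast effect sizes depend on the whole pipeline (windows,
  factor weights); only the calibrated fixation peak-to-peak d has a
  stated target.
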