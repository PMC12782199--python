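# Methods

## Protocol and spectral conventions

The stimulus frequency is stored as the exact rational 30/11 Hz (printed
2.727 Hz). Each 1.1-s analysis bin then contains exactly 3 stimulus cycles,
and 3·h cycles of harmonic h, so the sine/cosine regressors at 1F–4F are
mutually orthogonal over a bin and orthogonal to every other on-grid
frequency. Consequences relied on throughout:

- The unit-forgetting-factor recursive least-squares fit equals the ordinary
  least-squares fit, which equals the amplitude-scaled DFT coefficient
  (`dft_reference` is the independent oracle; agreement < 1e-8 is enforced in
  tests). A forgetting factor λ < 1 is supported as exponentially weighted
  least squares; the default is λ = 1 because no memory constant is required
  on stationary integer-cycle bins.
- Phase coherence across bins is automatic: every bin starts at an integer
  number of cycles, so a stationary response has the same coefficient in
  every bin.
- Phase convention, used identically by the simulator, the spectral module
  and the features: the fit is a·cos(2πft) + b·sin(2πft), the coefficient is
  c = a + ib, and θ = atan2(b, a) is a *delay* — A·cos(ωt − θ) ↦ A·e^{iθ}, so
  a later response has a larger θ.

The sampling rate defaults to 500 Hz (550 samples per bin, an integer); the
recording hardware's rate is not modeled. Trials are 12 bins (13.2 s); the
first and last bins are always discarded, leaving 10 usable bins, 10 trials
per condition per eye, i.e. 400 complex estimates (or equivalently 80
sine/cosine coefficient estimates per trial) per condition at 4 harmonics.

## Artifact rejection

Fixed order: (1) channels with strictly more than 15% of samples exceeding
30 µV in absolute value are replaced by the unweighted mean of their six
nearest good neighbors (Euclidean distance on the montage); (2) common-average
re-reference; (3) binning with edge-bin discard; (4) a bin is rejected for
all channels when strictly more than 5% of channels exceed 60 µV at any
sample within it, and a single channel-bin is rejected when strictly more
than 10% of its samples exceed 30 µV. All comparisons are strict, and
"exceeds" means |v| > threshold, since EEG is bipolar about its reference.
The 60-µV rule counts a channel as exceeding on any sample; a robust
per-channel statistic would be a reasonable alternative and is noted as a
sensitivity axis. An optional zero-phase 4th-order 0.3–50 Hz Butterworth
bandpass mirrors the acquisition filter; it is off by default because the
simulator already emits band-limited signals.

After spatial filtering, a (trial, bin) is usable in component space only if
*every* channel was usable in it: projection mixes channels, so one
contaminated channel contaminates all components. Eyes whose every bin is
rejected are flagged missing and skipped (propagated, not imputed).

## Reliable components analysis

Observations are the real and imaginary parts of per-bin harmonic
coefficients, stacked as separate real observations, which carries phase
information into the covariances while keeping the eigenproblem real
symmetric. Within each eye/condition block, observations are mean-centered
per channel; R_xx averages X_tᵀX_t over trials and R_xy averages X_tᵀX_u over
ordered pairs of distinct trials (symmetrized). Both conditions and all
control eyes are pooled into one covariance pair per cohort, giving a single
weight matrix W.

The filters maximize (wᵀR_xy w)/(wᵀR_xx w) — cross-trial covariance relative
to within-trial covariance — so the first component carries the most
trial-to-trial-consistent activity; an `invert_ratio` toggle exposes the
opposite reading for sensitivity analysis. R_xx receives diagonal loading
λ_reg·trace(R_xx)/n_channels with λ_reg = 1e-3 by default. Component sign is
fixed (largest-|weight| entry positive), eigenvalues are sorted descending,
and forward topographies are A = R_xx·W·(WᵀR_xx W)⁻¹. Training uses control
eyes only; patients and controls are projected through the same fixed W, so
group differences cannot arise from per-group sign flips.

## Features, SNR and masking

Per eye, the complex vector mean over all usable (trial, bin) cells is taken
per component × harmonic × condition, then encoded as (ρ, cos θ, sin θ);
phase is circular, so the (cos, sin) pair keeps it linear-model-friendly. A
zero mean yields (0, 0, 0) with a logged warning. Default dimensions give
144 features per eye; column order is pathway → component → harmonic →
encoding, with `age`, `sex_M`, `sex_unknown` (female reference) appended.

The per-eye SNR is sqrt(Σ_h |mean_h|²) / sqrt(Σ_h var(c_h)/n_h) over the
first component's harmonics, pooled over conditions — coherent signal over
the standard error of incoherent noise. This is this package's own
definition (the original study's exact rule is unpublished); it is monotone
in planted SNR, which the tests verify, and the default mask drops the
lowest 15% of eyes (an absolute threshold can be configured instead).

## Classification

Elastic-net logistic regression in the glmnet parameterization,
(1/n)·deviance + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), realized with scikit-learn's saga
solver via C = 1/(nλ). Defaults: α grid {0.1, 0.5, 0.9, 1.0} (including the
pure lasso), a 20-point data-driven λ path down to 1e-3·λ_max, selection at
the inner-CV deviance minimum (a 1-SE rule is available). For every outer
fold, standardization statistics and (α, λ) come from the training rows
alone; a construction test verifies that altering one held-out row cannot
change another held-out row's score. Reported coefficients come from a
full-data refit at the modal per-fold (α, λ), on the standardized scale
(coefficient × predictor SD).

Fold assignment is random but label-stratified by default: units (subjects
when grouped, rows otherwise) are shuffled within class and dealt
round-robin. Without stratification, pooled out-of-fold scores carry
fold-specific intercept offsets — each fold's training prevalence
anti-correlates with its held-out prevalence — which biases the pooled null
AUC well below 0.5 and would mask the pairing-leakage effect the grouped/
ungrouped comparison is designed to isolate. Out-of-fold scores are pooled
into a single ROC (per-fold averaging is available); threshold metrics use
score ≥ 0.5 ⇒ predicted patient, with patients as the positive class.

## Statistics

AUC is the Mann-Whitney statistic with ties counted ½ (tested against
exhaustive pair counting to 1e-12). DeLong variances come from placement
values; the paired variant includes the covariance of placements, the
unpaired variant adds the two variances. 95% CIs are normal-approximation on
the Δ scale, truncated to [−1, 1]; p-values are two-sided; Δ = 0 with zero
variance is reported as p = 1. The retained-feature comparison is a Pearson
χ²(1) on the 2×2 table with Yates continuity correction by default (the
uncorrected statistic is available); the correction is the default because
it reproduces the study's printed worked example (15/72 vs 12/72 →
χ² = 0.182, p = 0.67) exactly. Bonferroni correction is applied within
hypothesis families (pairing inflation, ON vs OFF, phase vs amplitude, SNR
masking), adjusted p = min(1, p·m).

## Synthetic cohorts: what they emulate and what they do not

One occipital source with a smooth, zero-mean, unit-norm scalp topography is
shared by the whole cohort (zero mean makes the planted signal invariant
under common-average re-referencing, so noise-free recovery is exact).
Per eye, harmonic h of condition P has complex mean A_h·s·exp(i(φ_h + δ)),
where (s, δ) are lognormal/Gaussian random effects drawn *per harmonic* and
shared between the eyes with correlation ρ (e = √ρ·z_subject + √(1−ρ)·z_eye).
Per-harmonic effects make subject identity multidimensional, as in real
recordings where each harmonic's amplitude and phase is idiosyncratic — this
is what twin-eye memorization in ungrouped CV feeds on. Patients receive a
multiplicative amplitude scale and an additive phase delay per pathway.

Defaults are calibration choices, not published values: base amplitudes
1.2/0.9/0.5/0.3 µV (ON) and 1.5/1.1/0.6/0.35 µV (OFF) across 1F–4F — an OFF
amplitude advantage; patient scales 0.90 (ON) and 0.75 (OFF); patient delays
0.40/0.30 rad; ρ = 0.7; random-effect SDs 0.35 (log-amplitude) and 0.30 rad.
The null-cohort experiments use stronger idiosyncrasy (SD 0.8, ρ = 0.9),
reflecting the large between-subject amplitude spread and high between-eye
similarity of real recordings; measured first-component features then
correlate ≈ 0.85 between the eyes of a subject. Background noise is 1/f
(exponent 1, 2 µV RMS per channel) synthesized spectrally, with a
closed-form expected noise-floor amplitude used as the Monte-Carlo oracle.
Blinks are 0.4-s, ≈120-µV frontal deflections; muscle bursts are 0.25-s,
50-µV-SD broadband bursts on a few channels; both are sized to trip the
rejection thresholds, which is all that matters downstream. Demographics:
patient/control ages ~N(59.3, 10)/N(61.7, 10), sex F/M/unknown at
0.44/0.49/0.07, patient mean deviation ~N(−6, 4) dB per eye.

Not modeled: stimulus optics and display, retinal/cortical biophysics,
multiple cortical sources, per-subject topographies, non-stationary
responses, eye-specific disease asymmetry. Passing tests therefore show
that the *pipeline* behaves correctly under the stated statistical
structure, not that real glaucoma data would yield any particular AUC.

## Monte-Carlo problem sizes

The seeded experiments in `ssvepipe.experiments` use a shortened protocol —
4 bins of 1.1 s (2 usable) at 250 Hz, 16 channels, 4 trials per condition —
which preserves the integer-cycle structure, the eye-pairing dependence and
the 1/f noise at a fraction of the cost; cohort sizes that matter
statistically (60+60 subjects for the leakage experiment, 20 seeds, 1000
null simulations, 100 recovery runs at SNR 10 with 32 channels and 20
trials) are kept at full size. The classifier in these loops uses α = 0.5,
an 8-point λ path and 3 inner folds. The full experiment grid
(3 pathways × 3 domains × 2 CV schemes × 2 masks = 36 fits) runs in
`analysis/04_classification_grid.py` on a 30+30 cohort.

## Known limitations

- The SNR definition and mask threshold are this package's stand-ins; real
  applications should calibrate them against their own noise model.
- The RLS recursion is exercised only in its exponentially-weighted
  batch-equivalent form; a streaming implementation would be needed for
  online use.
- DeLong CIs use the normal approximation, which is anticonservative for
  AUCs very near 0 or 1 on small samples.
- With only one planted source, components beyond RC1 are noise; their
  features act as pure distractors, which is harsher than real data where
  later components carry some structure.
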