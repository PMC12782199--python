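# ssvepipe

Frequency-domain analysis of steady-state visual evoked potentials (SSVEPs)
for ON/OFF-pathway case-control studies of glaucoma, built as a tested,
end-to-end pipeline: amplitude-threshold artifact rejection, recursive
least-squares (RLS) harmonic estimation on integer-cycle bins, reliable
components analysis (RCA) spatial filtering, amplitude/phase feature
construction, paired-eye cross-validated elastic-net classification, and
DeLong AUC-comparison statistics.

Because clinical EEG of this kind is rarely shareable, the package includes a
first-class synthetic cohort generator that emulates the statistical
structure the analysis assumes — a phase-locked occipital source responding
at harmonics 1F–4F of a 30/11 Hz (≈2.727 Hz) flicker, subject-level random
effects shared by the two eyes, 1/f background noise, and blink/muscle
artifacts — together with the ground truth needed for parameter-recovery
tests.

## Who this is for

Visual electrophysiologists and biostatisticians who want to (a) analyze
multichannel SSVEP recordings with a reproducible, leakage-aware
classification protocol, or (b) study the methodology itself: how much does
ignoring the correlation between a patient's two eyes inflate cross-validated
AUC, and what do phase features contribute beyond amplitude?

## The model in brief

Each 1.1-s bin holds an integer number of stimulus cycles, so fitting
a·cos(2πft) + b·sin(2πft) at each harmonic f by least squares is exact and
equals the DFT coefficient. The complex coefficient c = a + ib encodes
amplitude ρ = |c| and phase delay θ = atan2(b, a) (A·cos(ωt − θ) ↦ A·e^{iθ}).

RCA reduces 128 channels to K ranked components by solving the generalized
eigenproblem max_w (wᵀR_xy w)/(wᵀR_xx w), where R_xx pools within-trial
covariance and R_xy pools covariance between same-index observations of
distinct trials — incoherent noise cancels in R_xy, so leading eigenvectors
isolate stimulus-locked activity. Filters are trained on control eyes only
and applied unchanged to everyone.

Per eye, the cross-trial vector mean of each component × harmonic × condition
becomes three features (ρ, cos θ, sin θ): 2 pathways × 6 components × 4
harmonics × 3 = **144 features per eye**, plus age and sex. A logistic
elastic net (glmnet parameterization, (α, λ) chosen by inner cross-validated
deviance on training folds only) is scored out-of-fold under two schemes:
**paired eyes** (both eyes of a subject share a fold) and **ignore pairing**
(rows assigned at random). AUCs are compared with DeLong's paired/unpaired
tests; retained-feature counts with a Yates-corrected χ²; p-values are
Bonferroni-corrected within hypothesis families.

## Worked example

```python
from ssvepipe import ProtocolConfig, EffectSpec, simulate_feature_table
from ssvepipe.classify import make_folds, fit_elastic_net_cv, performance

table, rc_model, truth = simulate_feature_table(
    ProtocolConfig(), EffectSpec(), n_patients=10, n_controls=10, seed=11,
)
scheme = make_folds(table, k=10, grouped=True, seed=11)
result = fit_elastic_net_cv(table, scheme)
m = performance(result.oof_scores, result.labels)
print(f"AUC {m.auc:.2f}, accuracy {m.accuracy:.2f}, "
      f"retained {int(result.retained.sum())}/{len(result.coefficients)}")
```

With the default group effects (patients: OFF amplitude scaled ×0.75, ON
×0.90, phase delayed by 0.3–0.4 rad) this prints

```
AUC 0.96, accuracy 0.90, retained 101/147
```

— the paired-eye out-of-fold AUC, the accuracy at the 0.5 score threshold,
and how many of the 144 + 3 predictors kept a nonzero coefficient in the
full-data refit. The numbered drivers under `analysis/` run the
same stages against the on-disk container and print, e.g. (seed 20260921):

```
CV leakage: grouped 0.506, ignore-pairing 0.554 (gap 0.048)
phase-only effect: phase AUC 0.966 vs amplitude AUC 0.512
RCA recovery at SNR 10: 100/100 runs with |corr| > 0.95
DeLong: type-I 0.059, variance vs bootstrap rel. err. 0.036
```

i.e. cross-validation that ignores eye pairing inflates the null AUC by
about five points; a purely phase-borne group effect is invisible to
amplitude features; the control-trained spatial filter recovers the planted
scalp topography; and the DeLong test is calibrated.

`ssvepipe` is also a CLI: `ssvepipe simulate|preprocess|spectrum|rca|features|classify|compare|run`,
each with `--seed/--config/--out` (see `ssvepipe --help`).

## Layout

- `src/ssvepipe/` — library: `protocol`, `simulate`, `preprocess`,
  `spectral`, `rca`, `features`, `classify`, `stats`, `pipeline`, `io`, `cli`,
  `experiments`
- `analysis/01…05_*.py` — narrative drivers writing tables under `results/`
  (bulky intermediates go to `scratch/`)
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions, limitations
- `tests/` — pytest suite, including `test_acceptance.py` end-to-end checks
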