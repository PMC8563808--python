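# Methods

This note documents the models, parameters and numerical choices behind
`lfpstate`, and what the synthetic validation does and does not establish.

## Signal model of the synthetic generator

Each subject's hemisphere signal in one epoch is

```
x_h(t) = Σ_b  A_{b,h} · [1 + m·sin(2π f_m t + ψ_b)] · sin(2π f_b t + φ_b)
```

summed over the bands b ∈ {θ, α, β}, with the carrier `f_b` at the
integer-rounded band centre (6, 10 or 22 Hz, keeping the ±1 Hz modulation
sidebands inside the band at 1 Hz resolution), uniformly random phases, and
a slow amplitude modulation at `f_m ~ U(0.1, 1)` Hz with depth m = 0.3.
Each of the four contacts per hemisphere observes this shared oscillation
plus two independent noise terms: 1/f^γ background (γ = 1 by default,
synthesized by spectral shaping of white Gaussian noise and rescaled to a
target RMS) and white Gaussian noise (`noise_scale`, RMS 1.0 "µV-like"
unit by default). Sinusoids rather than narrowband-filtered noise were
chosen for their closed-form power (`A²/2` per unmodulated component),
which makes Parseval-style oracle tests exact.

A hemisphere flagged as bad receives additional broadband Gaussian noise at
40 × `noise_scale`. Healthy contacts carry oscillatory plus background
power well above the white-noise floor (contact RMS ≈ 2.8 at default
amplitudes), so the factor is set high enough that a corrupted contact
(RMS ≈ 40) exceeds ten times the cohort's median contact RMS — the
excessive-noise screening rule — by a wide margin.

Default acquisition: 2000 Hz sampling (configurable up to 44 kHz; a smoke
test exercises the full-rate path on a 5-s recording), three 60-s epochs
(PRE, MID, POST) separated and flanked by 2 s of padding so that filter
edge-guard trimming never shortens an epoch.

### The default cohort preset

Eight subjects with deterministic heterogeneity (ramps, not random draws,
so the ground truth is pinned by the spec itself and the seed only drives
noise realizations): overall amplitude scale 0.8–1.2 across subjects, base
band amplitudes 2.0. PRE and MID share identical amplitudes (no injected
mid-procedure effect). POST scales the left-beta amplitude by 0.35–0.65
across subjects (mean 0.5, i.e. the mean injected power drop is 75%) and
right-alpha by 1.5. The last subject carries a bad right hemisphere.
Baseline HDRS-17 values follow the reference clinical cohort (22.75 ± 1.50).

Clinical outcomes are generated as

```
hdrs_post = hdrs_baseline · (1 + s · Δβ%/100) + N(0, σ),  clamped to [0, 52]
```

with coupling slope s = 0.6 and outcome noise σ = 1.0 HDRS points. With the
preset's injected beta power drops (−88% to −58%) this produces a mean HDRS
decline of ≈ 44% and a positive beta–outcome correlation of moderate
strength — the regime the pipeline is meant to operate in. Both constants
are package defaults chosen once for realism, not fitted quantities.

### What the generator does not emulate

No stimulation artifacts, no line noise, no non-stationary drift, no
inter-contact covariance structure beyond the shared oscillation, no
volume-conduction or referencing physics, and no realistic absolute
amplitude/SNR calibration (no published figures exist for SCC LFP in this
setting; magnitudes were chosen for testability). Passing tests therefore
demonstrate correctness of the *computations* under a known generative
model, not performance on real recordings.

## Preprocessing

Chain order: decimate → zero-phase bandpass → DC removal → epoch edge
trim → within-hemisphere averaging → 1-s segmentation. Choices:

- **Decimation**: polyphase FIR resampling (handles non-integer ratios);
  anti-alias cutoff at 0.4 × target rate, 10 taps per polyphase branch per
  side. Target 1000 Hz.
- **Bandpass**: 4th-order Butterworth (order configurable), applied
  forward–backward (`sosfiltfilt`), so zero net phase and a squared
  magnitude response. The filter family is a field convention for
  "zero-phase bandpass"; 0.5–80 Hz defaults.
- **DC removal** subtracts each contact's whole-recording mean (not
  per-epoch means).
- **Edge guard**: epoch windows touching the first/last second of a
  recording are pulled off the boundary to keep filtfilt edge transients
  out; interior windows (the generator's default, thanks to padding) are
  untouched.
- **QC**: a hemisphere is excluded when any contact RMS exceeds 10 × the
  cohort median contact RMS. The rule is off by default at the library
  level (single-recording work) but on in the orchestrated pipeline, where
  the cohort context exists; it reproduces the manual exclusion such
  studies report and yields the N = 7 complete-case classifier cohort.

## Spectral features

Plain FFT of each raw (rectangular-windowed) 1-s segment; the segment mean
is removed first so the one-sided periodogram bins sum exactly to the
segment variance (Parseval normalization — the invariant every segment is
tested against). Band powers are sums over inclusive bin masks; at 1 Hz
resolution the printed band edges are unambiguous ({4..8}, {9..12},
{13..30} Hz). Sum rather than mean preserves Parseval additivity; any
monotone rescaling is irrelevant to the classifier after standardization.
No log transform by default; Hann windowing and log10 are config options.

## Classification

- Samples are 1-s segments, treated as exchangeable within subject;
  grouping is preserved by subject-wise cross-validation folds (outer and
  inner loops are both leave-one-subject-out at the group level).
- Features are standardized with training-fold statistics only.
- λ grid: 50 log-spaced values 1e-4…1e2; mixing 0.5 (configurable). The
  inner criterion is mean validation cross-entropy (smooth, matches the
  likelihood; AUC selection available); CE ties break toward the larger λ
  (parsimony).
- The chronologically later epoch is the positive class, fixing coefficient
  signs: a POST beta decrease appears as a negative beta coefficient.
- Solver: saga with warm-started path fits (tol 1e-6); λ = 0 uses
  unpenalized L-BFGS. Because saga can declare convergence before the
  unpenalized intercept settles under extreme shrinkage, every fit ends
  with an exact 1-D Newton polish of the intercept at fixed coefficients —
  a no-op when the solver converged, and it restores the analytic
  full-shrinkage limit (intercept = class log-odds) otherwise.
- Subject-level classifiers use stratified 5-fold outer / 5-fold inner
  segment splits (only one subject exists, so segments are the only
  resampling unit), requiring ≥ 10 segments per class.
- Repeated-measures ANOVA over two conditions is computed with statsmodels'
  AnovaRM; for two conditions F equals the squared paired t statistic,
  which the tests verify against an independent paired-t computation.

## Importance

A feature's importance is the fraction of inner-fold models — the models
refit at each outer fold's selected λ, one per inner fold — whose
coefficient survives the penalty. The replicate unit for the ANOVA is the
outer fold. Two deliberate choices:

- **Selection rule**: the literal reading "coefficient greater than zero"
  would permanently deselect features with negative effects, contradicting
  the very pattern of interest (a beta-power *decrease* driving the
  classifier). The default rule is therefore `|w| > 1e-8`; the positive
  sign rule remains available as `rule="positive"`.
- **Subset test**: one-way ANOVA across features on replicate importances,
  then Tukey HSD; the significant subset is the smallest prefix of the
  importance ranking whose members all dominate every outside feature at
  α = 0.05 (Bonferroni-style alternatives could be substituted; Tukey is
  the standard post-hoc for this design). When every replicate is
  identical the F statistic is undefined and the subset is empty.

Note that with a strongly separable cohort the inner criterion selects
minimal regularization, so several features can saturate at importance 1.0;
the dominant-feature statement is then about attaining the maximum, not
exceeding all others strictly. On noisy (real-scale) data the selected λ is
larger and the statistic discriminates more sharply.

The success-weighted variant multiplies importance by
`max(0, 2·(AUC_mean − 0.5))` — 0 at chance, 1 at perfect separation — a
declared, monotone weight for cross-contrast comparison.

## Clinical statistics

- Percent change is `100·(post − pre)/pre` for both HDRS and band power, so
  a positive correlation means decreases co-occur.
- Responders decline by strictly more than 50%.
- The slope test is the exact t-test of zero regression slope,
  `t = r√((n−2)/(1−r²))`, two-tailed with n−2 df.
- Family-wise correction: a min-p permutation procedure. Each permutation
  shuffles every test's outcome vector independently, recomputes the slope
  test p values, and records the family minimum; the corrected p is the
  fraction of minima at or below the observed p (identity permutation
  included, so p > 0). The marginal permutation p from the same draws is
  reported alongside; the corrected value can never fall below it, which
  is the anti-conservativeness guarantee the tests assert. 5000
  permutations by default. (A per-test-permutation + Benjamini–Hochberg
  variant would be a straightforward alternative; min-p was chosen as the
  fully specified reading of a permutation-based FDR threshold for a
  two-test family.)
- Per-feature n follows data availability: a subject missing a hemisphere
  drops out of that hemisphere's correlations only (n = 8 left / n = 7
  right in the default preset).

## Problem sizes in the validation suite

The multi-replicate checks (importance recovery over 40 seeded cohorts,
type-I calibration over 100/200 replicates) use 20-s epochs and, where the
LFP path is irrelevant, the clinical generator alone; the classifier null
and strong-effect checks use the full 60-s preset. These sizes are the
package's own choice of desk-scale validation conditions.

## Known limitations

- EDF export quantizes to 16 bits and requires whole seconds of data; the
  internal float32 container is the precision format.
- The elastic-net path relies on saga; at extreme separability with tiny λ
  convergence is slow, which is the main cost of the nested CV.
- The generator's deterministic subject ramps make cohort-level effect
  spreads reproducible but rule out studying between-cohort heterogeneity.
- Real-data quantities (AUCs near 0.73, beta–HDRS r ≈ 0.73) are not
  reproducible from synthetic data and are not targets of the test suite;
  only the directional pattern (PRE-POST ≫ PRE-MID at chance, left-beta
  dominance, positive beta–outcome coupling) is asserted.
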