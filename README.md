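# lfpstate

Intraoperative local field potential (LFP) brain-state biomarker analysis
for deep brain stimulation (DBS) studies, built around the subcallosal
cingulate (SCC) DBS setting in treatment-resistant depression.

## The problem

During DBS surgery, LFPs can be recorded from the freshly implanted
electrodes before any stimulation (PRE), midway through contact testing
(MID), and after extended bilateral stimulation at the therapeutic target
(POST). Whether this brief intraoperative exposure already changes the
brain's electrophysiological state — and whether that change predicts the
early antidepressant response — is a question for a small-sample,
high-dimensionality regime: a handful of subjects, six spectral features,
and repeated 1-s observations per subject.

`lfpstate` implements that analysis as a tested, reusable pipeline:

1. **Preprocessing** — decimation to 1000 Hz with anti-alias filtering,
   0.5–80 Hz zero-phase Butterworth bandpass, contact-wise DC removal,
   averaging of the four contacts within each hemisphere, and segmentation
   of each 60-s epoch into non-overlapping 1-s segments.
2. **Spectral features** — rectangular-window FFT per segment with Parseval
   normalization (power bins sum to the segment variance), summed over
   θ (4–8 Hz), α (9–12 Hz) and β (13–30 Hz): six features per segment
   (three per hemisphere).
3. **Classification** — elastic-net-regularized logistic regression
   between two epoch states, evaluated by nested leave-one-subject-out
   cross-validation. The penalized objective is

   ```
   min_{w,b}  (1/n) Σ_i log(1 + exp(-y_i (xᵢᵀw + b)))
              + λ [ α‖w‖₁ + (1-α)/2 ‖w‖₂² ]
   ```

   with mixing α = 0.5 and λ selected on an inner leave-one-subject-out
   loop by mean validation cross-entropy. Separability is reported as the
   mean AUC over outer folds.
4. **Feature importance** — the selection frequency of each feature: the
   fraction of inner-fold models (at each outer fold's selected λ) whose
   coefficient survives the penalty, with a one-way ANOVA + Tukey HSD test
   for a dominant feature subset and an AUC-weighted variant.
5. **Clinical arm** — HDRS-17 summaries (means, SDs, percent decline,
   strict >50% responder rule), pre/post repeated-measures ANOVA, and
   Pearson correlation of per-subject spectral percent change against HDRS
   percent change, with a min-p permutation family-wise correction
   (5000 permutations).

Because such intraoperative recordings are not openly downloadable, the
package ships a first-class **synthetic cohort generator** with known ground
truth: band-limited oscillations with slow amplitude modulation over 1/f
background noise, a bilateral 4-contact montage, three annotated epochs, a
left-hemisphere beta-power decrease from PRE to POST, a right-hemisphere
alpha increase, one subject with a noise-corrupted hemisphere, and a
depression-score change linearly coupled to the left-beta change. Every
stage of the pipeline is validated against this generator's ground truth.

## Worked example

```bash
lfpstate run-all --seed 1 --out runs/demo
```

simulates the default eight-subject cohort, runs every stage, and prints:

```
lfpstate run summary
====================

PRE-POST: AUC_mean = 1.000 (SD 0.000, N = 7)
PRE-MID: AUC_mean = 0.519 (SD 0.001, N = 7)
MID-POST: AUC_mean = 1.000 (SD 0.001, N = 7)
top importance 1.00: alpha_L, beta_L, theta_R, alpha_R, beta_R
HDRS-17: 22.75 -> 12.65 (44.4% decline, 1 responders)
beta_L: r(8) = 0.519, corrected p = 0.339
alpha_R: r(7) = 0.362, corrected p = 0.669
```

Reading these numbers: the PRE-POST contrast separates perfectly (the
preset halves the left-beta amplitude after "stimulation"), while PRE-MID —
into which no effect is injected — sits at chance. One subject's right
hemisphere is auto-excluded by the cohort RMS QC rule, so the group
classifier uses N = 7 complete-case subjects, left-hemisphere correlations
keep n = 8 and right-hemisphere ones drop to n = 7. The left-beta power
drop couples positively to the HDRS decline (r > 0); with the preset's
outcome noise the correlation is directionally correct but not significant
at this sample size. `runs/demo/` holds the feature table, per-contrast CV
results (all folds, λs and coefficients), importance scores, the clinical
report, and `report.json` with full provenance.

The same stages are available individually (`lfpstate simulate`,
`features`, `classify`, `importance`, `clinical`) and as library functions
(`lfpstate.nested_cv`, `lfpstate.importance_from_cv`, ...). Recordings
travel either as EDF+ (interchange, 16-bit) or as a raw float32 matrix with
a JSON sidecar (precision-bearing).

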