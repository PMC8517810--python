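# Methods

This note documents the modeling choices, the synthetic-data design, and
what the bundled tests do and do not establish.

## Problem framing

The pipeline predicts, five minutes in advance, the onset of sustained
intraoperative hypotension from a 20-s arterial-pressure snippet. All
processing happens at 100 Hz; 500-Hz input is decimated 5:1 by plain
subsampling (an optional zero-phase anti-alias filter exists but is off by
default so that every kept sample equals a source sample and runs are
exactly reproducible).

Windows are half-open `[start, end)` with 0-based indexing; time is
`t0 + i/rate`. The 2-s moving average is a *trailing* (causal) window — the
MA at time t uses only samples up to t — so every labeling decision could
be made in real time. An event is a maximal run of qualifying MA samples
(≥ 60 s under 65 mmHg, or over 75 mmHg for the negative class), reported
once; the event onset is the first qualifying sample.

"Five minutes previously" is anchored end-to-start: the 20-s input ends a
full 300 s before the 60-s outcome window starts, so a positive prediction
is a true 5-minute warning. Candidate outcome windows are enumerated on a
20-s stride grid (configurable) plus one window at each detected event
onset; a grid window is positive when the MA stays under 65 for its entire
60 s, negative when it stays over 75 throughout, otherwise indeterminate.
Indeterminate and QC-failing pairs stay in the manifest but never reach the
models.

## Artifact screening

The four exclusion criteria (missing values; pressure over 200 / under
20 mmHg; max−min range under 20 mmHg; adjacent-sample jump over 30 mmHg)
use strict inequalities — a value exactly at a threshold passes — because
the criteria are phrased as "over"/"under". The 20-s and 60-s windows of a
pair are screened independently and the pair is dropped if either fails.
Pairs adjacent to a missing sample are not evaluated for the jump
criterion; the missing-value criterion already excludes them. Segments are
never repaired or imputed.

## Beat processing

Systolic peaks are local maxima with a 0.3-s refractory distance and
10-mmHg prominence (both configurable; no specific peak detector is
canonical for this task). Cycles run foot-to-foot, the foot being the
pressure minimum between consecutive peaks; the edge cycles are recovered
when their feet lie inside the segment and the resulting cycle is at least
3/4 of the median cycle length, so cut partial cycles stay excluded. Each
cycle is linearly interpolated to 100 samples. The 30×100 matrix keeps the
most recent 30 cycles (pre-truncation) or prepads zero rows, so real beats
always occupy the last rows.

Waveform scaling for both network inputs is the fixed affine map
`(x − 20)/180` clipped to [0, 1], anchored at the physiologic QC bounds.
Per-segment min-max scaling was rejected because absolute pressure level is
precisely the information the task needs.

Per-beat features use the un-scaled mmHg values: systolic pressure = cycle
maximum, diastolic = cycle minimum, beat area = trapezoidal integral over
the cycle (pressure above 0 mmHg), per-beat MAP = area/length, systolic
time = foot-to-peak. A cycle's sample range is start..end inclusive, so a
1.0-s constant beat at 100 mmHg integrates to exactly 100 mmHg·s. PPV of a
pulseless (zero-PP) segment is defined as 0. Robust scaling uses the
linear-interpolation quartile convention; features with zero IQR are
flagged degenerate and scale to 0. Quartiles come from the training fold
only.

## Models and training

The training backend is a small reverse-mode autodiff engine on NumPy
bundled as `stepop.nn`, with fused hand-written backward passes for
convolution, batch norm, pooling and the LSTM (backpropagation through
time); all layer gradients are pinned against central differences in the
test suite. Training uses float32 by default (float64 available via
config), a single CPU, and is bit-deterministic given the seed.

Printed constants of the training recipe: AdamW with β₁ = 0.9, β₂ = 0.99,
learning rate 10⁻⁴; binary cross entropy with class weights 1 (negative)
and 20 (positive), applied in the loss only (no oversampling); inner 90/10
patient-level split for model selection, best checkpoint by inner AUPRC.
The loss is computed from logits via softplus identities and equals the
probability-space definition exactly; probabilities at 0/1 are clipped at
1e-7 in the probability-space form.

Architecture and schedule choices that are this package's own defaults:
CNN with three conv blocks (kernel 7→5→3, filters 16→32→64, max-pool 4
each), batch norm and ReLU per block, global average pooling, FC 64 → 1;
LSTM hidden size 64 per direction, three bidirectional layers, final
forward/backward hidden states concatenated into FC 64 → 1; zero-padded
beat rows are fed as-is (no masking); batch size 256; weight decay 0.01;
epochs 20 (15 at the desk-scale config — enough for convergence on the
synthetic cohort at the fixed 10⁻⁴ learning rate). These appear under
`non_paper_defaults` in every emitted run manifest.

The logistic baseline is scikit-learn's L2-penalized logistic regression;
the penalty is chosen by 5-fold cross-validation over C ∈ 10⁻³…10³ with
folds grouped by patient to prevent leakage, then refit on the full
training fold (solver tolerance 1e-8 so fits are reproducible to high
precision).

## Ensemble and evaluation

α is searched on the grid {0, 0.01, …, 1} by AUPRC on the inner 10%
tuning patients, ties broken toward the smallest α. Because the grid
contains both endpoints, the tuned mix can never score below either single
model on the tuning set; the analogous ordering on validation data is
expected but stochastic.

AUPRC is the average-precision estimator (step integration over ranked
positives, tied scores grouped into one step), not trapezoidal PR
interpolation — the two differ and the step form is the standard
implementation. AUROC is the tie-corrected rank statistic. Precision at a
sensitivity target takes the highest threshold whose sensitivity reaches
the target, without interpolation. Bootstrap CIs resample 50% of segments
without replacement, 1000 times (2.5th/97.5th percentiles); with-replacement
and patient-level resampling are available flags. Single-class resamples
are redrawn.

## Synthetic cohort design

No generative description of real arterial waveforms is available to this
package, so the simulator is a deliberately simple, fully controllable
construction — not a validated hemodynamic model. Its purpose is to make
every pipeline stage testable and the prediction task genuinely learnable:

- **Beats**: a fixed two-bump template (systolic peak + dicrotic wave) on a
  foot-to-foot cycle, chord-corrected so both feet sit at zero and scaled
  so the discrete beat mean equals the local MAP exactly. Heart period has
  AR(1) jitter; 20-s segments hold roughly 20–40 beats across the default
  heart-rate range, exercising both the padding and truncation branches of
  the beat matrix.
- **MAP trajectory**: per-patient baseline drawn from 85–100 mmHg plus slow
  two-tone wander (±2 mmHg). Each hypotensive dip declines linearly from
  baseline toward a prodromal level (68 mmHg) over the pre-onset drift
  (default 420 s), then plummets to the dip floor (48–60 mmHg) over 30 s at
  the scheduled onset — mirroring the typical monitor picture of a gradual
  decrease followed by an abrupt drop, and keeping the detected
  moving-average crossing close to the scheduled onset.
- **Episode structure**: auto-generated schedules draw 0–2 clusters per
  record, each with 1–3 sustained dips (4–10 min) separated by brief
  partial recoveries. Sustained, recurrent episodes are what make the
  5-minute-ahead task learnable: a sizable share of positive windows is
  preceded by already-low pressure, alongside harder onset-anchored windows
  whose inputs lie in the gradual drift. This reproduces the qualitative
  class-conditional feature structure of real cohorts (positives with
  markedly lower MAP and diastolic pressure, shorter beats, higher PPV
  five minutes ahead).
- **Physiologic couplings**: as MAP falls below baseline, heart rate rises
  (+35% at full deficit), mean pulse pressure falls (−25%) and beat-to-beat
  pulse-pressure variability grows, so hypotension has a morphological
  signature beyond mean level.
- **Artifacts**: each exclusion criterion has a matching injectable class
  (missing gaps, >200/<20 spikes, ≥22-s flat stretches, >30-mmHg steps) at
  a configurable Poisson rate, with every injected span logged for oracle
  tests.
- **Determinism**: every record derives its RNG from (seed, patient index);
  identical configs give byte-identical cohorts.

What the simulator does **not** emulate: real beat-morphology diversity
(arrhythmia, damping, drug effects), measurement drift, respiratory
modulation, or the very low event prevalence of real operating-room
cohorts (the desk-scale cohort runs at a validation prevalence around
0.2–0.35 so that a few thousand segments suffice for stable training).
Passing tests therefore demonstrate that the pipeline's mechanics,
contracts and training dynamics are correct — not that the trained weights
transfer to patients.

## Problem sizes

The default desk-scale configuration (`small_config`) simulates 50 patients
× 30 min at 100 Hz (~2800 usable segment pairs), trains 15 epochs, and
completes in about four minutes on one CPU; `tiny_config` (8 patients,
2 epochs) is the smoke/reproducibility scale. Bootstrap resamples default
to 200 at desk scale (1000 in the API default).

## Known limitations

- The peak detector assumes reasonably clean pulses; QC-passing but
  morphologically exotic segments could slice poorly (such segments are
  dropped and logged, never silently imputed).
- The enumeration stride couples prevalence to event duration; it is a
  config knob, and reported metrics always carry the realized prevalence.
- With very small cohorts the inner 10% tuning set can be a handful of
  patients, making α noisy; the tuning-set dominance property still holds
  by construction.
- Batch-norm statistics make network predictions depend on training-batch
  composition; determinism is guaranteed only for identical configs and
  seeds on the same BLAS.
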