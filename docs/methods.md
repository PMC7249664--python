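# Methods

`drivestress` analyses skin potential response (SPR) and ECG recordings from
simulated highway driving, comparing a manual and an autonomous scenario on a
fixed 40 km track with four stress-inducing tasks. Because no public
recordings exist for this protocol, the package ships a synthetic session
generator that reproduces the statistical structure the analysis relies on;
every downstream stage is validated against that generator's ground truth.

## Synthetic sessions

A session is a pair of hand SPR channels, up to three ECG channels and the
track schedule, all uniformly sampled at a configurable rate.

**SPR model.** The artifact-free signal is

```
spr(t) = tonic(t) + sum_k a_k * s(t - t_k) + e(t)
```

with a linear tonic drift, white measurement noise `e`, and evoked phasic
transients with biexponential kinetics
`s(t) = exp(-t/tau_d) - exp(-t/tau_r)` (unit peak; `tau_r = 0.5 s`,
`tau_d = 3 s`). These time constants are standard phasic-electrodermal
kinetics: a sub-second rise and a few-second recovery. Event times `t_k`
follow a two-rate Poisson process — one rate inside task intervals, a lower
one outside — and amplitudes `a_k` are normal, truncated at zero.

Scenario defaults encode the qualitative manual/autonomous contrast the
analysis is designed to detect: manual driving shows *frequent, moderate*
phasic peaks (6/min in tasks, 2/min outside, mean 0.8 mV) while autonomous
driving shows *sparse but larger* peaks (2.5/min in tasks, 0.3/min outside,
mean 1.6 mV). These rates and amplitudes are free parameters of the
generator; the defaults were chosen once as plausible magnitudes for palmar
skin potential and are deliberately overlapping enough that classification
is imperfect.

**Hand channels and artifacts.** Each hand channel is the clean signal plus
independent noise plus motion-artifact bursts: 0.6 s white-noise bursts
under a Hann envelope, 2 mV scale, 1.5/min in the manual scenario and none
in the autonomous one (hands rest on the knees). Bursts never overlap in
time and are assigned to exactly one hand (except with a small configurable
simultaneous probability, default 0.05), reflecting the observation that
steering engages one hand at a time.

**ECG.** Beats are placed sequentially with instantaneous rate
`baseline + increment·1[in task] + jitter` (manual default 83 + 4 bpm,
autonomous 75.5 + 0.5 bpm, jitter sd 2 bpm) and rendered as a sum of four
Gaussians (Q, R, S, T; R amplitude 1 mV). Three derivations with different
gain/noise emulate a chest vest where one lead is cleanest.

**Cohorts.** Per-subject random effects — a heart-rate offset (sd 8 bpm) and
log-normal scales on tonic level and evoked amplitude (sd 0.2/0.25 in log
units) — are shared across a subject's two sessions so scenario contrasts
stay paired. Scenario order alternates across subjects to counterbalance
order effects. All generation is driven by `numpy` Generators seeded from a
single cohort seed; identical seeds give bit-identical sessions.

**What the generator does not emulate:** non-stationary artifact spectra,
electrode drift and detachment, respiration/HRV structure beyond white
rate jitter, ectopic beats, and any coupling between SPR and HR. Passing
tests therefore demonstrate that the pipeline recovers the *programmed*
structure, not that it would reach the same numbers on human recordings.

## Motion-artifact fusion

The two hand channels are fused into one cleaned SPR by a soft
energy-weighted combination. Local energy is the moving average (default
2 s window) of the squared first difference — differencing keeps the slow
tonic level from dominating the weights. With energies `E_L, E_R` and
exponent `p` (default 2):

```
w_L = (E_R^p + eps/2) / (E_L^p + E_R^p + eps),   out = w_L·L + (1-w_L)·R
```

Weights are convex at every sample, so the output always lies between the
two inputs; equal energies give the plain average (the `eps/2` regularizer
makes the all-quiet case exactly symmetric); a burst on one hand drives the
output toward the other. `p = 2` makes the switch decisive without hard
switching. Simultaneous two-hand bursts are passed through unhandled — they
are rare by construction and surface as occasional false positives
downstream. Fusion quality is measured against the generator's clean
reference via trace RMS and the variance of each difference-to-reference.

## Features and classification

The fused SPR is normalized per track (subtract the track mean, divide by a
standard deviation). For cross-scenario comparison the divisor is the
*manual* track's std of the same subject, putting both scenarios of one
subject on a common scale; the mean is always the track's own. The
normalized signal is segmented into 15 s blocks every 5 s (10 s overlap;
trailing partial blocks dropped), and each block is summarized by variance,
energy (mean of squares, so `energy - variance = mean²`), mean absolute
value, and mean/max absolute first derivative scaled by the sampling rate.
Energy is a mean rather than a sum so its value is independent of the
sampling rate. A block is labeled "stress" when its half-open interval
intersects any task interval.

The classifier is an RBF-SVM. Features are min-max scaled to [0, 1] on the
training rows only (test values clip), the majority class is subsampled to
balance, and cost/width are selected by a seeded grid search
(C ∈ {0.1…100}, γ ∈ {0.01…10}, 5-fold stratified CV). Evaluation is
leave-one-subject-out: scaler and model for each fold are fit on the
remaining subjects only. Predicted sequences are relabeled before scoring:
an isolated positive run (default maximum length 1) flanked by negatives is
flipped to negative; the pass never creates positives and is idempotent.
Accuracy is reported after relabeling.

The permutation control deserves a note: with the default track, ~34% of
blocks are positive, and the accuracy of an uninformative classifier with
positive-prediction rate `q` is `0.66 - 0.32q`, not 50%. The control
therefore permutes labels on a class-balanced subsample, which pins the
chance level at exactly 50% whatever `q` is.

## Heart rate

R peaks are detected with Pan–Tompkins-style stages: 5–25 Hz band-pass,
derivative, squaring, 150 ms moving-window integration, a per-10 s adaptive
threshold (0.3 × segment maximum), refinement to the band-passed apex, and
a 250 ms refractory period. When several derivations are available the one
with the highest 5–25 Hz band-power ratio is used (ties break to the lowest
index). Instantaneous HR is 60/RR assigned at the later beat, gated to
(20, 250) bpm before linear interpolation onto a 1 Hz grid; interval means
(per task, outside tasks, whole track) are arithmetic means of the 1 Hz
samples in each class. HR is never used as a classifier input — the
manual/autonomous HR difference partly reflects the physical activity of
steering, which would confound a stress comparison.

## Summary statistics and published tables

Task-level SPR statistics: per-task RMS divided by whole-track RMS (the
whole-track RMS *includes* task intervals), the std ratio between
concatenated in-task and out-of-task samples, and moving local RMS for
timeline plots. Across-subject comparisons use the two-sided paired t-test
with df = n − 1. The published per-subject tables (whole-track stress
percentages and mean HR by interval class, 13 subjects × 2 scenarios) are
packaged verbatim as CSV fixtures; the report module recomputes their row
means. Two quirks of the printed HR table are preserved and flagged rather
than corrected: the manual block labels two rows "task 4", and one manual
task-2 entry (128 bpm) is inconsistent with its printed row mean — that row
is excluded from mean-reproduction checks via a `consistent` flag.

## Problem sizes and numerical choices

Analyses that only need SPR run at 50 Sa/s (the full-rate 1 kSa/s sensor
stream is heavily oversampled for electrodermal kinetics, which live below
a few Hz); ECG analyses run at 250 Sa/s. The bundled experiments use
8-subject training cohorts for the leave-one-subject-out study (the
acceptance script averages three replicate cohorts), an 8-subject two-
scenario test cohort for the stress-percentage contrast, a 6-subject
two-scenario cohort for HR recovery, and 50 sessions for the fusion
quality suite — sizes chosen so the full suite reruns in a couple of
minutes while keeping Monte-Carlo noise well inside the asserted bands.
Other fixed choices: population variance in block features; half-open
`[start, end)` intervals everywhere, so boundary touches are not overlaps;
fusion ε = 10⁻¹²; session CSVs written at 17 significant digits and parsed
with round-trip float precision.

## Known limitations

* The fusion residue on synthetic sessions (≲0.1% RMS) is far below what
  mixed real artifact/EDA signals produce; the synthetic bursts are
  spectrally distinct from the phasic transients, which flatters the
  energy-based weighting.
* LOSO accuracy on default cohorts (~66–69%) is a property of the chosen
  generator overlap, not an estimate of performance on human data.
* The isolated-positive relabeling rule is the simplest consistent with its
  description; the run-length threshold is configurable.
* The generator's constant-speed time mapping makes task intervals identical
  across subjects; real sessions vary in task timing and duration.
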