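# Methods

## Problem setting

A transhumeral TMR patient controls a five-motion prosthesis (hand
close, hand open, wrist rotation, elbow flexion, elbow extension) from
five bipolar sEMG channels over the reinnervated muscles, one channel
designated per motion. When the channels are *coupled* — one motion
attempt produces comparable amplitude on several channels, typically
because two reinnervation targets are heads of the same muscle —
per-channel amplitude thresholding cannot separate the motions.
Pattern recognition over all channels jointly can, but its raw decision
stream misfires during contraction transients. This package implements
the full decision pipeline and the post-processing that fixes the
transient problem, together with a simulator that reproduces the
coupled-signal regime so every component can be exercised and scored
against ground truth.

## Signal path

Recordings are dense mV-valued sample × channel matrices. The real-time
path band-passes to 80–400 Hz; we use a 4th-order Butterworth, applied
forward–backward (zero phase) for offline analysis and as a causal
single pass when a streaming realization is wanted. Only the band was
specified by the clinical system; order and realization are our choice,
and the zero-phase default keeps window timestamps aligned with the
envelope ground truth.

Analysis windows are 137.6 ms with 50 % overlap. Window length in
samples is `round(window_ms·fs/1000)` and the hop is
`round(length·(1−overlap))`: 256/128 samples at the embedded 1860 Hz
(137.6 ms is evidently the duration that encodes a 256-sample power-of-
two buffer), 138/69 at the 1000 Hz rehabilitation recorder. Exact
reproduction of the stated duration is impossible in integer samples, so
rounding is fixed rather than configurable, and a trailing partial
window is discarded.

## Features

MAV, WL, ZC and SSC per channel, concatenated channel-major into a
4 × n_channels vector. ZC counts strict sign flips (`x_k·x_{k+1} < 0`,
so exact zeros never count, avoiding double counts across zero runs)
with swing ≥ ε; SSC counts interior samples whose two adjacent
differences share a sign, larger step ≥ ε. The deadband convention for
ZC/SSC was not specified by the source system; the default ε = 0.01 mV
(half the simulator's baseline-noise RMS scale) suppresses noise-floor
chatter, and ε = 0 recovers the textbook definitions used by the test
oracles. MAV and WL scale linearly with gain; ZC/SSC at ε = 0 are
gain-invariant — both properties are tested.

## Classifier

LDA as the shared-covariance Gaussian Bayes rule. Fitting computes
per-class means and the pooled within-class covariance
(scatter/(N−K)), ridged by `reg_lambda·(trace/d)·I` with
`reg_lambda = 1e-6` so the covariance is invertible even with collinear
features; the trace scaling makes the ridge unit-free. Priors default
to class frequencies — uniform under the balanced training protocol.
Prediction is the argmax of
`g_k(x) = μ_kᵀΣ⁻¹x − ½μ_kᵀΣ⁻¹μ_k + ln π_k`, ties broken toward the
earlier label for determinism. No rest class is trained: the 35 s
session covers exactly the five motions, and stillness only ever arises
from post-processing. Tests pin the implementation to a brute-force
Gaussian log-density oracle and cross-check against scikit-learn.

## Post-processing

*Majority vote*: output t is the modal label of the last min(t+1, L)
raw decisions, current included. The cited scheme leaves ties
unspecified; we resolve toward the previous output (hysteresis), then
label order.

*MAV threshold switch*: with raw decision C_i and V_i the MAV of the
classified motion's channel, the output is C_i iff `D_i = V_i − T_i > 0`,
else STILL. The comparison is strict ("higher than"), so V = T stays
still. V_i is measured on the same band-passed window the features came
from — raw vs. filtered was unspecified, and using the filtered window
keeps the gate consistent with what the classifier saw. The two
post-processors are deliberately not composed; they were evaluated as
alternatives and the library mirrors that.

The standard threshold set ST is 0.2 mV per motion with 0.1 mV for
wrist rotation (the weaker deltoid site); LT and HT scale it by 0.8 and
1.2.

## Protocol

Training: five motions × 7 s, prompted back to back; the first 4 s of
each segment is discarded (transient + settling) and the last 3 s
windowed and labelled — 42 windows per motion at 1860 Hz. The "about
7/4/3 s" of the clinical protocol are fixed to exact values for
determinism.

Rehabilitation assessment: each weekly session holds every motion ~5 s;
the motions × channels grid entry (m, c) is channel c's windowed MAV
averaged over motion m's hold, then over sessions. Rest gaps are
annotated out. The per-motion independence score divides the intended
motion's entry in its designated channel's column by the largest other
entry in that column: > 1 means amplitude control could separate the
motion, ≈ 1 or below means coupling defeats it. Grid values are stored
in mV; only the optional plot normalizes (per grid, recorded in the
grid metadata).

## Simulator

Each channel is `E_c(t)·carrier_c(t) + noise_c(t)`: a unit-variance
Gaussian carrier band-passed to 80–400 Hz and renormalized, an
independent white Gaussian baseline (RMS 0.02 mV), and an envelope
summing trapezoidal per-motion activations (0.4 s linear onset/offset
ramps — transients exist in the source system but their duration is not
stated) weighted by a motions × channels coupling matrix in mV. A
Gaussian of scale σ has E|x| = σ√(2/π), so coupling entries set steady
MAVs directly. Schedule entries' core intervals (ramp + hold) may not
overlap, but an offset decay may cross-fade into the next onset, which
is how the back-to-back training session keeps each kept 3 s tail fully
steady. Everything is reproducible from one integer seed.

Coupling acts on envelopes only (co-activation), not on carriers
(cross-talk): the clinical picture attributes the coupling to
co-contraction of reinnervated sites more than 2 cm apart. The default
matrix encodes that picture qualitatively: hand open drives the
elbow-extension channel at 0.8× its own amplitude and elbow extension
drives the hand-open channel at ~0.67× (two heads of one triceps), hand
close ↔ elbow flexion couple at 0.4× (two heads of one biceps), all
other cross terms sit near the noise floor, and the wrist-rotation
(deltoid) channel is weaker overall. Steady moderate-effort amplitudes
are set at roughly twice the standard thresholds (0.45 mV vs 0.2 mV;
0.25 mV vs 0.1 mV on the deltoid channel) — the operating point at
which a therapist-adjusted amplitude gate is reliable during holds,
consistent with thresholds that are preset from moderate-contraction
MAV and tuned until holds pass cleanly. True patient coupling
magnitudes are only qualitatively known; these values are a realistic
encoding, not a fit.

What the simulator does *not* model: motor-unit biophysics,
volume-conduction cross-talk, electrode lift-off and socket motion,
fatigue drift, or day-to-day nonstationarity. Passing tests therefore
demonstrate the algorithmic claims (transient-error suppression by
amplitude gating, coupling-robust classification) under the stated
statistical model of coupled sEMG, not clinical performance.

## Evaluation

Windows are partitioned by ground truth: *steady* if entirely inside a
hold, *rest* if touching no motion footprint, *transient* otherwise —
ramps, decays, and any boundary-straddling window (the conservative
assignment, since those windows mix states). Steady accuracy counts
STILL as an error during a hold; the transient error rate counts only
wrong-motion outputs (STILL is the desired transient behaviour);
windows overlapping two motions' footprints accept either motion.
ARAT scoring itself is an observer judgment and is never automated:
task scores (0–3) are inputs, the package computes final scores (mean
of three trials), condition totals, and percent increases over a
baseline condition. The measured totals of the motivating case study
ship as a reference table (`CASE_STUDY_TOTALS`).

## Problem sizes and numerical choices

The simulation studies (tests and `scripts/acceptance.py`) use one 35 s
training session and one ~35 s five-hold assessment recording per
replicate at 1860 Hz, three seeded replicates — enough for every rate to
be estimated from ~1500 windows while the full suite runs in well under
a minute of compute. Determinism: all simulator randomness flows
through `numpy.random.default_rng(seed)`; LDA ties break by label
order; vote ties by hysteresis then label order; decision streams are
written with fixed float formatting so identical seeds give
byte-identical files.

## Known limitations

- The streaming (causal-filter) path is provided but the evaluation
  harness scores the offline zero-phase path only.
- Majority vote and threshold switching cannot be composed in one run;
  the source system evaluated them separately.
- The LDA variant in the source system's citation trail may differ in
  regularization detail; we implement the standard shared-covariance
  Bayes form.
- Human functional outcomes (task times, completion) are inherently
  outside simulation scope; only their scoring arithmetic is
  reproduced.
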