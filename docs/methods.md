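# Methods

## The problem

`stressbci` re-implements, as a tested pipeline, a subject-dependent
EEG-based mental-stress classification study: adolescents (with and without
autism spectrum disorder) alternate between timed mental-arithmetic stress
induction and slow-breathing recovery while 16 channels of 10–20-montage
EEG are recorded at 125 Hz, and classifiers are trained to decode the
current condition — *baseline*, *stressor*, *unguided breathing* or
*guided breathing* — from short EEG windows. The original recordings were
never publicly released; everything signal-level in this package therefore
runs on a synthetic-session generator whose defaults encode the study
protocol, while the published per-participant result tables ship as CSV
fixtures so the behavioral/comparative statistics can be recomputed
exactly.

## Session protocol

A session is 120 s of baseline followed by four blocks, each a 90 s
stressor and a 200 s breathing period; breathing alternates unguided,
guided (≈6 breaths/min entrainment), unguided, guided. A 5-point stress
self-report follows every stressor and every breathing period; the report
given after the breathing period of block *k* serves as the pre-stressor
score of block *k*+1, so block 1 has no pre/post pair. Rest periods of
configurable length (default 30 s — the source protocol does not state
one) model the self-report prompts; rest EEG is generated but never
labeled, so labeled data per session is 120 s baseline, 360 s stressor,
400 s unguided and 400 s guided — the same class imbalance direction as
the study.

## The synthetic EEG generator

Per frequency band *b* ∈ {theta 3–7 Hz, alpha 8–14 Hz, beta 15–30 Hz}, one
unit-RMS source runs for the whole session (white noise band-passed with a
zero-phase order-4 Butterworth). During a segment with condition *c* the
source is projected to the scalp through a unit vector

  u(b,c) ∝ q_b + v · r_{b,c}

where q_b and r_{b,c} are columns of two per-participant orthonormal
matrices and *v* (`spatial_variability`, default 1) sets how strongly a
mental state reconfigures the active network. v = 0 reduces the generator
to pure gain modulation of one fixed topography (the classical
event-related (de)synchronization picture); v > 0 gives each condition a
distinct spatial covariance — the structure CSP and the downstream
classifiers actually exploit, and the reason four-class decoding is
possible after per-channel normalization. The projection is scaled by the
profile's per-condition band multiplier m(b,c) and by a per-band amplitude
(theta 8, alpha 12, beta 6 µV RMS). Because u is unit-norm, channel-summed
band power scales exactly as m², which the spectral-fidelity tests assert
(ratio within 20 % on 200 s segments with noise off).

Default multipliers: stressor suppresses alpha (0.6) and raises beta (1.8)
with a mild theta increase (1.1); breathing raises theta/alpha (unguided
1.3/1.4, guided 1.6/1.8) and lowers beta (0.9 / 0.6). These encode the
qualitative directions reported for mental stress and slow-breathing
interventions; their magnitudes are the package's chosen "strong contrast"
regime and are deliberately not tuned per experiment.
`ParticipantProfile.with_separation(s)` scales both the multiplier
deviations and `spatial_variability`, giving a one-parameter
class-separation dial used only for difficulty sweeps (s = 0 makes
conditions statistically identical).

On top of the band sources: channel-independent 1/f-power background
(5 µV RMS × `noise_level`), a 0.3 Hz sinusoidal drift of 40 µV (the study
reports strong sub-1 Hz drift, which motivated its 1 Hz high-pass), and a
60 Hz mains component of 5 µV. Condition transitions are instantaneous;
windows never straddle segment boundaries, so no ramp is needed. Identical
(profile, seed) pairs give bit-identical sessions.

Self-reports: relaxed-state scores are drawn near 2 ("somewhat relaxed",
SD 0.6), post-stressor scores add a shift of +1.4 plus N(0, 0.5) noise,
rounded half-up and clipped to 1–5. The shift/SD defaults make an
11-participant cohort's pre-vs-post Wilcoxon test reject at α = 0.05 in
the vast majority of replicates, mirroring the study's clearly significant
behavioral effect without attempting to reproduce its exact Z values
(impossible without the raw reports).

What the generator does **not** emulate: volume-conducted forward-model
topographies, ocular/muscle/cardiac artifacts, non-stationarity within a
condition, inter-block drift of electrode impedance, and any genuine
physiological link between trait anxiety and signal properties. Passing
end-to-end tests therefore show that the pipeline's machinery recovers the
structure the generator encodes — not that these accuracies would transfer
to real adolescent EEG.

## Preprocessing

The band-pass contract is attenuation-based: ≥ 20 dB at 0.5 Hz and 60 Hz,
≤ 1 dB ripple over 2–45 Hz, zero phase. The default realization is a
windowed-sinc FIR (Hamming; transition 1 Hz at the 1 Hz edge, 5 Hz at the
50 Hz edge; ~495 taps at 125 Hz) applied centred, with reflection padding,
so annotations need no delay compensation; a forward-backward Butterworth
design of configurable order is available, but meeting 20 dB at 60 Hz
*and* ≤ 1 dB at 45 Hz with a 50 Hz corner needs roughly order 10, so the
FIR is the default. Filtering twice changes passband RMS by < 5 %
(idempotence test).

Recording rejection is a pure gatekeeper standing in for the study's
impedance-based exclusions: any near-constant channel, or ≥ 2 channels
whose RMS exceeds 100× a reference (cohort median when available), rejects
the session with a reason string. Cropped training tiles each labeled
segment with non-overlapping windows (1 s default; 5 s supported); the
default session yields 120/360/400/400 windows per class. Splits are
seeded and stratified: 80:20 for the SVM stage, 70:30 for the deep stage.
If overlapping strides are configured, stratification alone no longer
prevents temporal leakage; the default stride equals the window length
precisely to avoid that.

## FBCSP-SVM

Nine contiguous 4 Hz bands span 4–40 Hz (order-4 zero-phase Butterworth
per band; 1 s windows are too short for narrow FIR kernels). Per band and
condition pair, CSP filters are the generalized eigenvectors of
(C₁, C₁+C₂), where class covariances are averages of trace-normalized
per-window covariances with 1e-6·I shrinkage; the m = 2 most
class-1-dominant and m = 2 most class-2-dominant filters are kept, and
W᠎ᵀ(C₁+C₂)W = I holds by construction. Features are
log(var/Σvar) over the 2m projections per band (scale-invariant), 36 per
window, fed without feature selection to an RBF-SVM with γ = 1/360 and
C = 1.6 (scikit-learn). The four reported pairs are guided–stressor,
baseline–stressor, unguided–guided, unguided–stressor. A brute-force
whiten-then-eigendecompose oracle checks the CSP solution to 1e-8 on
random instances. Chance level for a permutation null is the majority
class share, so null checks balance classes first (0.5 binary, 0.25
four-class).

## Deep models

Seven multiclass architectures run on a compact in-package numpy neural
network engine (dense, LSTM, 1D/2D/depthwise/separable convolution,
max/average pooling, batch normalization, dropout; hand-derived backward
passes verified against central-difference gradients; Adam; softmax
cross-entropy — the standard choice for a softmax head, as the loss is not
otherwise specified). Everything is seeded: same config + data gives
bit-identical weights.

* **LSTM stacks** (1/2/3 layers): 50, 50+40, 50+40+40 units over the
  window read as 125 time steps of 16-dim channel vectors; dropout 0.5;
  dense 20 (sigmoid); dropout 0.5; dense 10 (ReLU); dense 4 (softmax).
* **Deep ConvNet**: four conv–max-pool blocks (temporal kernels (1,5),
  pool (1,2), ELU) with 25/50/100/200 filters; block 1 adds a spatial
  convolution spanning all 16 channels. The printed spatial kernel size
  "(1, 64)" contradicts both the cited source architecture and the
  16-channel montage and is treated as a typo for a full-height kernel.
* **Shallow ConvNet**: block 1 only with temporal kernel 13, then square →
  average-pool (1,8) → log — a learnable band-power + spatial-filter
  analogue of FBCSP.
* **EEGNet**: 8 temporal filters of length 64 ('same' padding), depthwise
  spatial convolution over the 16 channels with depth multiplier 2,
  separable convolution of length 16, batch-norm/ELU/average-pool/dropout
  as in the original compact design, whose values fill every constant the
  description leaves open.
* **LSTM-FCN**: parallel 8-unit LSTM branch (dropout 0.8; no dimension
  shuffle) and a temporal-convolution branch of 128/256/128 filters with
  kernels 8/5/3 (batch-norm + ReLU, global average pool), concatenated
  (8 + 128 = 136) into the softmax head.

Parameter counts of every build are pinned against independent
layer-formula hand counts. Training defaults: Adam, learning rate 0.001,
batch 200. The study-scale schedule is 1000 epochs
(`TrainingConfig.full_fidelity()`); the package default is 100, and the
test suite uses 30 for sweeps. A training dynamic worth knowing: on the
synthetic sessions the two-layer LSTM separates the stressor and the two
breathing classes within ~20 epochs but passes through a plateau in which
*baseline* is merged with its nearest neighbour, although the classes are
perfectly linearly separable; the split resolves between roughly 40 and a
few hundred epochs depending on the seed, which is one reason the original
1000-epoch budget is generous rather than excessive. Subject-dependent
training (one model per participant) is the default, matching the study's
eleven per-participant models.

## Evaluation and statistics

Confusion matrices are true × predicted counts over the four classes;
class-wise sensitivity/specificity/precision come from one-vs-rest
reductions, with undefined rates reported as NaN rather than 0.
Precision–recall curves are one-vs-rest on the softmax scores.

Nonparametric conventions (stated because the source leaves them open):
average ranks for ties; zero differences dropped from the Wilcoxon
signed-rank test; all tests two-sided. Wilcoxon Z always comes from the
tie-corrected normal approximation, signed so that a stress *increase* is
negative; p is exact (scipy) for n ≤ 25, else asymptotic. Mann–Whitney
uses the exact distribution for tie-free samples with n ≤ 20 per group,
otherwise the tie-corrected normal approximation *without* continuity
correction — the convention under which the published ASD-vs-neurotypical
p = 0.566 reproduces exactly (with continuity correction it is 0.633;
exact enumeration gives 0.648). Spearman uses average-rank tie handling.

Display rounding is half-away-from-zero to 2 decimals; full precision is
kept internally. Published averages that do not equal the mean of their
own printed cells (the 3-layer LSTM 72.26 vs 72.25; the EEGNet table
average 60.21 vs 60.22 and the 61.18 quoted in the running text, which
equals that model's baseline class cell) are flagged in reports, never
silently reconciled, and excluded from exact-agreement checks.

## Pipeline and formats

EDF is written by a minimal in-package 16-bit writer (1 s records,
per-channel physical scaling from the observed extrema, quantization step
(max−min)/65535) and read back through MNE's native EDF reader — every
file the package writes is thus independently parsed by a third-party
implementation. Annotations travel in a TSV sidecar (onset_s, duration_s,
label; overlap-validated), behavioral records in CSV. `run_experiment`
chains the stages with per-stage seeds, wall-clock and SHA-256 output
checksums in a JSON manifest; a failing model family is recorded and
skipped, not fatal. Identical configs reproduce identical checksums.

## Problem sizes

Deliberate desk-scale choices, made once: classifier checks use one full
synthetic session (1280 one-second windows; two-layer LSTM at 100 epochs)
plus reduced-duration sessions (60/45/100 s segments, 640 windows, 30
epochs) for the separation sweep and permutation nulls; the CSP oracle
comparison uses dozens of random 16-channel instances; behavioral power
uses 200 replicate cohorts of 11. The acceptance script mirrors these
sizes.

## Known limitations

* The generator's class structure is low-rank (one source per band and
  condition); real EEG mixes many sources and the reported synthetic
  accuracies are not predictions for real data.
* The NN engine is CPU/NumPy; it is exact but not fast, so study-scale
  (1000-epoch) training is available but not the default.
* EDF writing truncates to whole seconds and stores a fixed nominal start
  date; neither matters for round-tripping this package's own sessions.
* The multiclass-SVM variants the study mentions discarding are available
  via `restrict_classes` + custom `SVMSpec` but are not part of default
  reports.
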