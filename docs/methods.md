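# Methods

This note documents the models, parameter choices and numerical conventions
behind `somnistage`, and what the synthetic experiments do and do not
demonstrate.

## Synthetic polysomnography

The generator exists so that every downstream stage — QC, filtering, feature
extraction, training, fusion, evaluation — can be exercised end to end with a
known ground truth.

**Stage sequences** come from a first-order Markov chain over the five
classes (wake, N1, N2, N3, REM). The default transition matrix makes stages
sticky (self-transition 0.60–0.88) with physiologically ordered moves (wake ↔
N1 ↔ N2 ↔ N3, REM entered mostly from N2 and exited toward wake/N1) and a
wake-dominated initial distribution; a default night is 960 epochs (8 h).
These numbers are plausibility choices, not fits to any cohort.

**Signals** are sums of amplitude-modulated sinusoids plus Gaussian broadband
noise, rendered per 30 s epoch per channel. For each oscillation band
(center, bandwidth, amplitude) a frequency is redrawn uniformly within the
band each epoch, and the sinusoid is modulated by `1 + 0.25·sin(2π f_m t)`
with `f_m` ∈ [0.1, 0.4] Hz. Stage templates follow textbook AASM spectral
physiology, with amplitudes in µV:

| stage | EEG | EOG | EMG (10–20 Hz band) |
|---|---|---|---|
| wake | 8–12 Hz alpha, 30 | small slow activity, 15 | 25 (high tone) |
| N1 | 4–7 Hz theta, 25 | slow rolling, 20 | 12 |
| N2 | theta 25 + 12–14 Hz spindle bursts (Poisson 3/epoch, 1 s, 30) | 10 | 8 |
| N3 | 0.5–2 Hz delta, 60 | delta bleed, 20 | 5 |
| REM | theta, 22 | large slow deflections, 60 | ≈0 (atonia) |

Background noise is 8 µV on EEG/EOG and 5 µV on EMG. Because the per-frame
min–max normalization (below) erases absolute amplitude, stage information is
deliberately carried by spectral *shape*: the EMG tone is a band bump over a
flat noise floor rather than a raw amplitude level.

**Artifacts.** Three kinds are injectable — a full-night electrode drop, a
temporary drop over an epoch range, and a post-removal segment running to the
end of the night. Affected epochs are overwritten with a constant plateau on
the affected channel only. The declared physical acquisition maximum defaults
to 250 µV per channel; saturation plateaus default to 1.6× that value
(400 µV). The factor is 1.6 rather than just above 1 because the per-epoch
rejection rule runs on *filtered* data: a 51-tap FIR cannot realize its
0.3 Hz high-pass edge sharply, so a constant plateau retains only ≈ 0.70–0.76
of its amplitude after the forward–reverse double pass (measured
|H(0)|² = 0.755 at 125 Hz), and a 1.2× plateau would fall back under the
physical maximum after filtering.

**What the generator does not emulate:** real EEG microstructure
(K-complexes, sawtooth waves, vertex waves), inter-subject variability,
gradual stage transitions, movement and sweat artifacts, or mains
interference. Stage classes are far better separated than in clinical data.
Consequently, a high held-out accuracy on synthetic nights certifies the
pipeline's correctness — features carry the stage signal, training converges,
labels align with epochs — but says nothing quantitative about performance on
real recordings.

## Quality control

Thresholds derive from the declared physical acquisition maximum carried in
the EDF header. The whole-night rule drops a channel when its mean absolute
amplitude strictly exceeds half that maximum; the per-epoch rule excludes an
epoch when both EEG channels, or both EOG channels, or the EMG channel
strictly exceed the full maximum. Comparisons are strict (`>`); ties are
measure-zero in practice. If one member of a pair was already dropped for the
night, the pair test degrades to the surviving channel alone, consistent with
salvaging single-channel nights; if a whole pair (or EMG) is gone the record
is rejected at channel derivation with an explicit reason.

Filtering is applied to the whole night before epoching, so the 51-tap edge
transients occur once at the recording ends rather than inside every epoch.
The epoch grid is 0-based and half-open: epoch *k* covers [30k, 30(k+1)) s.

## Filtering and resampling

Band-pass filters are 51-tap ("50th order") Hamming-window FIR designs —
0.3–45 Hz (C3/C4), 0.3–12 Hz (EOG), 0.3–20 Hz (EMG) — applied forward,
reversed, applied again and reversed. The double pass cancels the phase
(verified by zero-lag cross-correlation) and squares the magnitude response
(verified against the designed filter's transfer function). At 51 taps the
transition bands are wide (≈ 8 Hz at 125 Hz sampling); in particular the
0.3 Hz high-pass edge passes much of the DC of a saturated plateau, which the
QC design above accounts for.

Resampling to the 100 Hz analysis rate uses polyphase rational resampling
with the built-in anti-aliasing low-pass at the target Nyquist; a 30 s epoch
always yields exactly 3000 samples (off-by-one outputs from extreme rational
approximations are edge-trimmed/padded).

## Spectral stacks

Per epoch and derived channel: frames start at samples 0, 90, …, 2790 (32
frames, 900 ms step, 38-sample overlap), each windowed by a 128-point
(symmetric) Hamming window and transformed with a 128-point FFT; the
magnitudes of one-sided bins 0–31 are kept. The bin width is
100/128 = 0.78125 Hz, so bins 0–31 span 0–24.2 Hz. Values are FFT magnitudes
(not power, not dB): the subsequent normalization makes the distinction
nearly moot. Each time frame is independently min–max normalized,
`(v − min)/(max − min)`, so every non-degenerate frame attains 0 and 1; a
degenerate frame (max = min, e.g. an all-zero epoch) maps to all zeros. DC
(bin 0) is included among the 32 bins; it is near zero after the 0.3 Hz
high-pass anyway.

Channel derivation: EEG is the C3/C4 average when both survive QC, else the
survivor; a dropped EOG channel is replaced by its partner in both slots; EMG
passes through. The stack order is fixed as (EEG, EOG-L, EOG-R, EMG).

Mode-*i* inputs concatenate the stacks of epochs t−i+1 … t along the time
axis and flatten frequency × channel into 128 columns with column index
= 32·channel + bin. This flattening order is arbitrary but fixed and
bit-stable; any fixed order is equivalent for learning. The first i−1 epochs
of a night, and any epoch whose i-epoch context contains a QC-excluded epoch,
produce no sample (skipped and logged, never padded).

## Classifier and training

A single unidirectional LSTM (forget/input/output gates and candidate,
zero-initialized biases, Gaussian weights with 1/√fan-in scale) consumes the
(i·32)×128 sequence one 128-dimensional row per step; the final hidden state
feeds a dense layer to five logits. Unidirectionality keeps the model causal
in the epoch stream (usable online); dropout defaults to 0 for the LSTM and
is available on the readout only.

The loss is softmax cross-entropy with per-class weights `N/(5·n_k)`
(inverse frequency normalized to mean 1; absent classes get weight 0 and a
warning), multiplying each sample's term — doubling all weights exactly
doubles the cost. Optimization is Adam with moment decay 0.9/0.999, learning
rate `1e-3·10^(−floor(epoch/50))` floored at 1e-6, at most 200 epochs, and
two early-stopping rules evaluated on the testing cost after each epoch:
five successive absolute differences below 1e-5 (plateau) or five successive
increases (rise). Non-finite costs abort with a diagnostic.

Mini-batches follow a subject-grouped procedure: permute subjects, split
them into groups, permute each group's pooled samples and pack them into
full-size batches, then concatenate the per-group remainders, pack those,
and discard the final short batch. Every emitted batch has exactly the
configured size and the batches partition the retained samples (fewer than
one batch-size of samples is discarded). Subject permutation, sample
permutation and weight initialization are all driven by explicit seeds.

The full-scale configuration (512 cells, batch 1024, 200 epochs) is exposed
as the `full` profile. The `desk` profile used by the tests and the
reproduction script — 64 cells, batch 128, six training subjects of 340
epochs (~2000 samples), one held-out 360-epoch subject, 15 epoch cap — is
sized for a single CPU core; the forward/backward passes are exact
regardless of scale.

## Fusion and evaluation

Fusion re-examines only epochs the mode-3 network labels N2 or N3, taking
the label of whichever network has the larger maximum probability; equal
maxima resolve to mode 3 (the primary network). Softmax probabilities, not
logits, are compared. Epochs for which only one network has a sample (night
edges: the deeper-context model starts later) fall back to the available
network and are flagged (`model-3-only` / `model-2-only`).

Metrics are computed only on QC-retained, prediction-covered epochs, and
every report carries the coverage fraction. Undefined quantities — the
sensitivity of a stage absent from the truth, or Kappa when the marginals are
concentrated in one class (Pe = 1) — are reported as missing values, never
as 0, so averages cannot be silently inflated.

## EDF storage

EDF files use 1 s data records (integer sampling rates), 16-bit samples over
a symmetric digital range, so the quantization step is physical-range/32767.
The declared acquisition maximum — the quantity QC thresholds derive from —
is written into each signal's transducer header field (`acq_max=<v>uV`), and
the stored physical min/max are widened when a signal (an injected
saturation artifact) exceeds the declared maximum, so saturated amplitudes
survive a round trip instead of being clipped. The reader prefers the
transducer annotation and falls back to the header physical maximum for
files written by other software.

## Known limitations

- Synthetic stages are nearly separable; desk-profile results are an upper
  bound of pipeline correctness, not a performance claim for clinical PSG.
- The EDF implementation covers the subset of the format this pipeline
  needs (uniform 1 s records, five named channels, µV units).
- The from-scratch LSTM runs on CPU only; full-scale (512-cell,
  million-sample) training is out of practical reach here, which is why the
  `full` profile exists but is not routinely run.
- No notch filtering, ocular-artifact regression or ICA: out of scope by
  design.
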