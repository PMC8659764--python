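# Methods

This note documents the models and procedures implemented in
`sleepglove`, the parameters that matter, the design choices made where
the problem was genuinely open, and what the synthetic test-bed does and
does not establish.

## Signal model

A night consists of three channels from a finger-worn sensor: one
photoplethysmogram (PPG) at 100 Hz, peripheral oxygen saturation (SpO2)
at 1 Hz, and 3-axis accelerometry at 50 Hz reduced on-device to a
per-minute movement count. All analytics are reported at one-minute
resolution plus whole-night statistics.

## Block codec

The device stores recordings in 4 KB flash blocks of 25 rows × 157 bytes
with an empirical-Huffman token grammar (see `FORMAT.md`). The design
constraints were: bit-exactness (the codec is the transport of record, so
any loss would propagate to every analysis), independence of block order
(flash blocks are transmitted as they free up, not chronologically), and
~9 bits per PPG sample in the common delta regime so an 8 h night stays
in the low-megabyte range.

Two points were open and resolved as follows:

* **Scale-factor semantics.** Deltas wider than 8 bits are factored as
  `scale × quotient` over {2, 4, 8, 16, 32, 64, 128, 256}. Only exact
  factorings are used (smallest admissible scale); anything else is
  re-sent as an absolute value. A rounding quotient would have made the
  codec lossy, contradicting its central guarantee, at a saving of only
  6 bits per rare event.
* **Row layout.** Rows 2–25 drop the 4-byte sample counter but keep their
  own 2-byte useful-bit count; tokens never straddle rows. 25 × 157 =
  3925 bytes, zero-padded to the 4096-byte flash block.

Garbage-coded samples (outside the 18-bit converter range) are the only
sanctioned loss: the sample counter advances, the value is dropped, and
the decoder marks the sample invalid so downstream minutes covering it
are nulled.

## Pulse detection and cardiac analytics

The PPG is z-scored and systolic peaks are found by topographic
prominence (default 0.8 on the z-scored signal) with a 300 ms refractory
period. The prominence default was chosen so that a dicrotic notch at
40% of pulse amplitude — the template the generator uses — can never
reach threshold, while genuine pulses at physiologic amplitudes always
do; the refractory period additionally blocks within-pulse secondary
peaks at any amplitude. Ectopic intervals deviating more than 30% from a
centered running median of 5 are masked and interpolated for rate
averaging only; rhythm rules always see the raw series.

Per minute (intervals are assigned to the minute of their starting
pulse):

* **Bradycardia** — mean inter-pulse interval > 1200 ms (HR < 50 bpm);
  **tachycardia** — mean interval < 500 ms (HR > 120 bpm). The "episode"
  is read as the minute's average interval crossing the threshold,
  matching the averaging step that produces the minute HR; a
  single-interval variant is available as `episode_rule: any`.
* **AF / PVC** — with `m` the minute's mean interval, any interval
  `> m + 50 ms` flags a possible atrial fibrillation, any interval
  `< m − 50 ms` a possible premature ventricular contraction; one
  detection flags the minute. Inequalities are strict, so an interval at
  exactly ±50 ms is no detection. The alternative reading — successive
  interval differences rather than deviation from the mean — is exposed
  as `deviation_rule: consecutive`. Note the rule's known behaviour at
  long base intervals: any modulation proportional to the interval (e.g.
  respiratory sinus arrhythmia at ±4%) exceeds a fixed 50 ms margin once
  intervals pass ~1250 ms, so bradycardic minutes tend to co-flag AF.

## Breathing rate

Respiration modulates the PPG three ways: baseline wander (RIIV),
pulse-amplitude modulation (RIAV) and pulse-interval modulation (RIFV).
Each series is extracted per pulse, cubic-interpolated to a uniform 4 Hz
grid, and analysed in 32 s or 64 s windows (Welch, Hann, 50% overlap)
over the respiratory band 4–60 breaths/min. The per-window rate is the
dominant spectral peak with parabolic refinement; its quality index is
the fraction of band power in the peak bin ±1 (≈1 for a clean tone,
≈1/n_bins for noise, floored at 0.2).

Window estimates are fused by a Kalman smoother: breathing rate is a
scalar random-walk state (process s.d. 0.5 bpm per window step) observed
once per modulation with measurement variance `(1 bpm)² / quality`, then
smoothed backward (Rauch–Tung–Striebel). The filter initializes at the
first usable inverse-variance combination, so a constant input is an
exact fixed point. The state-space and quality index are this package's
design; only the fusion principle (quality-weighted Kalman smoothing of
the three modulations) is taken as given.

Longer windows trade responsiveness for spectral resolution: at 4 Hz and
64 s the Welch bin spacing is ≈1.9 bpm (≈3.8 bpm at 32 s), which with
parabolic refinement puts the clean-signal error well under 1 bpm and
makes the 64 s estimate at least as accurate as the 32 s one — an
ordering the acceptance suite asserts.

## Apnea / hypopnea detection and classification

* **DAP detection.** The per-pulse peak-to-trough amplitude is
  interpolated to 4 Hz; its baseline is a 150 s centred running median.
  A DAP (decrease in amplitude fluctuation) event is a maximal run at
  least 10 s long where the envelope stays below 70% of baseline
  (depth threshold 0.3); runs closer than 5 s are merged. The threshold
  sits between the respiratory amplitude modulation (±20%) and the
  shallowest injected event (35%), and the 150 s baseline cannot be
  dragged down by a sub-minute event.
* **Desaturation.** SpO2 drops of ≥3 percentage points below the median
  of the preceding 120 s of artifact-free readings (artifact = the
  encoder's ≤37% sentinel). The 3-point magnitude follows standard
  clinical scoring practice and is configurable.
* **Coupling.** A DAP is apneic/hypopneic iff a desaturation onset falls
  in the 20 s window *starting at* the DAP onset ("left-centred"); a
  centred window is available behind `coupling_mode`. Without a coupled
  desaturation the DAP is a control event — this is the mechanism that
  keeps specificity high on healthy nights, and removing all
  desaturations provably drives every DAP to control.
* **Features.** 37 per-event features from a 65 s window centred on the
  event: 10 pulse-rate-variability time-domain, 12 PRV spectral (LF
  0.04–0.15 Hz, HF 0.15–0.4 Hz, LF/HF sympathovagal balance, normalized
  powers, peak locations, spectral entropy), 8 DAP morphology (duration,
  depth, area, nadir, slopes, time-to-nadir, baseline level), 7 SpO2
  descent statistics. The exact list is a documented reconstruction
  (`sdb.FEATURE_NAMES`), registry-driven so it can be swapped without
  code changes. Events whose window is truncated by the recording edge
  are excluded.
* **Classifier.** Univariate ANOVA selection to the 5 most discriminative
  features, standardization, then a Gaussian-kernel SVM with kernel scale
  0.56 (gamma = 1/0.56²). Selection is integral: a kernel this narrow
  only behaves as a local classifier in low dimension, and 0.56 equals
  the fine-Gaussian scale heuristic √P/4 at P = 5. Three pairwise tasks
  are evaluated — central vs obstructive, CA vs CH, OA vs OH — with
  10-fold stratified CV after downsampling every class to the minority
  count; each task reports TPr, FPr, accuracy and AUC.

## Sleep staging

Movement derivative per 20 ms accelerometer step:
`D = (|Δx| + |Δy| + |Δz|) / δ` (a signed sum would let axis movements
cancel, so absolute differences are used). A movement is a rising-edge
crossing of D above the hardware threshold (default 15 device-units/s:
an order of magnitude above the sensor-noise derivative, well below a
0.5-unit single-axis movement step at δ = 20 ms). Counts are tallied per
minute into N_j; after the night ends, with m_N and σ_N the whole-night
mean and sample (n−1) standard deviation:
N_j > m_N + 3σ_N → awake, N_j > m_N + σ_N → light sleep, else deep
sleep. Strict inequalities; σ_N = 0 makes every minute deep sleep. A
consequence of the sample estimator worth knowing: a single outlying
minute among n can only reach the awake band when (n−1)/√n > 3, i.e.
n ≥ 11. The module accepts either raw 50 Hz accelerometry or the
device's pre-computed per-minute counts (the codec's movement tokens).

## Synthetic night generator

The generator is the study bed for every claim the test suite makes. It
builds the PPG from a template pulse (Gaussian systolic peak, dicrotic
notch at 40% amplitude) placed at interval-driven times: HR 60–72 bpm by
default, respiratory modulations at the scenario's breathing rate
(amplitude ±20%, interval ±4%, baseline wander 50 counts), pulse
amplitude 500 counts on a 6000-count baseline with 2-count Gaussian
noise, integer-quantized to the 18-bit device range. That scaling keeps
clean-night deltas inside the signed 8-bit coder regime, which is the
operating point of the file-size claim. Events: apneas scale amplitude
by 0.4 (depth 0.6), hypopneas by 0.65; central events suspend the
interval modulation (no breathing effort), obstructive events append a
20 s post-event sympathetic-surge surrogate (intervals shortened 15%);
desaturations of 5 (apnea) or 3 (hypopnea) points lag event onset by
5–12 s with a 4 s descent. Arrhythmic minutes use 1300 ms / 450 ms
intervals (brady/tachy), random +250 ms jumps (AF-like) and premature
beat + compensatory pause pairs (PVC-like). Movement bursts are 0.5-unit
square steps on one axis.

The generator is deterministic under a fixed seed and its event ledger
is serialized with each recording, so every analysis can be scored
against ground truth.

**What passing tests show — and don't.** The suite demonstrates that
each algorithm recovers the structure it assumes, at clean signal
quality, with event contrasts the generator explicitly encodes (e.g. the
obstructive-vs-central surge). Real nights add motion artifacts,
waveform variability, probe detachment, co-occurring pathologies and
class overlap that the generator does not model; clinical performance
cannot be inferred from these tests, only implementation correctness.

## Problem sizes and numerical choices

Test and acceptance runs use 0.5–3 h synthetic nights (the file-size
measurement uses the full 8 h session, ≈2.9 M PPG samples); these sizes
exercise every code path at full sampling rates. Other conventions:
sample (ddof = 1) standard deviations throughout; strict inequalities at
every published threshold; LF/HF set to 0 when HF power vanishes;
minutes with fewer than 2 pulses are unanalyzable (null labels); windows
truncated by a recording edge yield no estimate; duplicate blocks keep
the first copy; corrupt blocks become gaps that null exactly the minutes
they touch.

## Known limitations

* Pulse-interval modulation aliases when the breathing rate approaches
  half the pulse rate; the fusion's quality weighting mitigates but does
  not remove this.
* The AF/PVC ±50 ms rule is amplitude-blind and co-flags long-interval
  minutes (see above); it reproduces the published rule faithfully
  rather than improving on it.
* Subtype labels in the per-minute table require a trained classifier;
  a single unlabeled night reports events as `unclassified`.
* EDF input is not implemented; CSV is the plain-text interchange
  format.
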