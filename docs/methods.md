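# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package. Everything quantitative below is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Signal model and preprocessing

LFPs are treated as two uniformly sampled channels (left/right STN) at an
acquisition rate of 422 Hz. The canonical path band-passes 8–100 Hz and
decimates to 211 Hz; force plates are decimated to 100 Hz (when acquired
at 1000 Hz) and low-passed at 2 Hz to remove jerky non-gait transients.

Filter family, order and phase behavior are not dictated by the problem,
so they are package choices: zero-phase forward-backward order-4
Butterworth (`sosfiltfilt`, reflect padding). Zero phase matters because
the decoder's window/label alignment is temporal; any group delay would
systematically shift the 2-s label horizon relative to its 5-s input
window. A consequence of Butterworth two-pass filtering is soft band
edges: content within a few hertz of a corner loses a few percent per
pass. Tests therefore assert pass-band fidelity in the band interior
(e.g. 50 Hz within 5 %) and ≥ 20 dB stop-band attenuation, not flatness
at the corners. Decimation uses `scipy.signal.decimate` (order-8
Chebyshev-I anti-alias at 0.8 × the new Nyquist, zero phase), which keeps
in-band tones within 2 %.

Recordings are generated and consumed inclusive of the session endpoint
(`n = round(duration · fs) + 1` samples), so a 100-s session carries
labels at t = 5.0, 5.1, …, 100.0 — exactly 951 windows.

## The weight-shift label

Force channels are divided by body weight, making labels robust to weight
change across visits. Per sample the two unit-normalized plates are merged
by keeping the higher one, with left-plate values mirrored about 0.5; high
merged values mean weight on the right, low on the left, and lower-force
(foot-off) samples are disregarded.

The windowed "change in force" statistic is implemented as the **total
variation** of the merged trace over a sliding 2-s window (sum of absolute
successive differences, emitted every 0.1 s). This is the one formula in
the package that is a reconstruction rather than a published definition:
total variation is zero for a motionless stance, grows with both the
amplitude and the number of shifts, and is invariant to the left/right
plate convention (swapping plates maps m → 1 − m and leaves it unchanged).
Labels are normalized per participant by the maximum 2-s shift across the
three visits; the scaling constant is retained so later visits reuse it.

## The synthetic participant

Clinical recordings of this kind are not publicly deposited, so the
generator produces sessions with the statistical structure the decoder
assumes. Per visit (~100 s by default; 60 s in the desk-scale profile):

* **Stance**: a smoothed square wave at 0.5 Hz (raised plateaus emulate
  single-support phases; `tanh(3 sin)/tanh 3`), ramping from/to quiet
  standing (0.5) over the first and last 2 s, held at 0.5 during
  configurable freezing episodes. Stepping vigor is modulated
  sinusoidally (depth 0.5, period 20 s, seeded phase): participants pace
  themselves, and without vigor variation the label would be nearly
  constant and rank correlation against it undefined.
* **Forces**: right plate = stance × body weight (700 N default), left
  the complement, plus 5 N white noise, floored at 0. With zero noise the
  plates sum exactly to body weight.
* **LFP**: per channel, unit-RMS 1/f^χ colored noise (χ = 1.5 on the
  first visit) + enveloped narrow-band carriers + white noise (SD 0.1).
  Default oscillations: alpha (10.5 ± 2.5 Hz, amplitude 0.2), beta
  (13–36 Hz, amplitude 0.9), low-gamma (40–60 Hz, amplitude 0.15). The
  amplitudes make beta the dominant oscillatory component, the
  characteristic off-medication parkinsonian STN spectrum; this matters
  for the band-attribution analysis, whose output-variance probe tracks
  each band's absolute power (see Limitations).
* **Coupling**: envelope(t) = amp · (1 + sign · gain · intensity(t)),
  clipped at 0, where intensity is |d stance/dt| smoothed over 2 s — the
  same horizon as the label. Default: beta only, gain 0.8, sign −1
  (movement-related beta desynchronization).
* **Visits**: three per participant, independent noise, shared coupling
  and contacts; the aperiodic exponent drifts by +0.1 per visit by
  default, emulating the slow non-movement spectral change that motivates
  the relative (divided) features.

What the generator does **not** emulate: stimulation artifacts, tremor
(4–6 Hz), cross-channel correlation of the two STNs beyond their shared
envelope, non-stationary carrier waveforms, or realistic force-plate
micro-dynamics. Passing tests therefore demonstrate correct mechanics and
recoverability under the stated assumptions, not clinical performance.

## Architecture choices

Published hyperparameters are kept as defaults where stated (lr 1e-5,
batch 16, max 2000 epochs, patience 100, L1 loss, 3 LSTM layers, no
biases outside squeeze-and-excitation). Sizes that are not published are
reconstructions, all overridable via `ModelConfig`: 16 conv filters per
lead, kernel 53 samples (~0.25 s at 211 Hz), pooling 21/10 samples, SE
reduction 4, LSTM hidden 32 per direction, head width 16.

Open points resolved as package conventions:

* Block order within feature extraction is conv → batch norm → square →
  pool. Batch norm learns only a scale (a shift is an additive bias,
  which the architecture forbids here).
* Division pairing: within each lead's filters, the first half are
  numerators and the second half denominators; the guard ε = 1e-6 keeps
  division defined at vanishing power. The division block is
  parameter-free and width-preserving, so the no-division variant has
  exactly the canonical parameter count; removing SE or the bi-LSTM
  strictly reduces it.
* When the bi-LSTM is ablated the head's first convolution consumes the
  feature map with a single group.
* Initialization is uniform fan-in from the build seed. The final dense
  layer's weights are made non-negative at init: the head input is
  non-negative (post-ReLU averages), so this keeps the output ReLU in its
  linear region instead of starting dead with zero gradient.
* "Improvement" for early stopping is a strict decrease of the epoch-level
  validation L1 (per-window mean); ties in best-epoch selection resolve
  to the earliest epoch.

The network and its gradients are implemented directly on numpy arrays
(`n2gnet.nn`): grouped/depthwise convolutions run via FFT for long
sequences and via einsum for short ones (both paths agree to machine
precision and are tested against each other), the bi-LSTM uses hand-written
backpropagation through time, and optimization is standard Adam. All
gradients are finite-difference-checked in the suite.

## Desk-scale profile

Full-scale training (2000 epochs on ~950 windows) is impractical for a
test suite on one CPU, so experiments and tests use a documented reduced
profile (`n2gnet.pipeline`): 60-s sessions, 8 filters per lead, pooling
53/40, LSTM hidden 12, head width 8, learning rate 1e-3, ≤ 60 epochs with
patience 15, and a 0.3-s training/validation stride (test evaluation keeps
the full 0.1-s grid). These sizes are the package's choice of a
single-CPU operating point; the published-scale settings remain the
library defaults.

## Evaluation

MAE/MSE are computed on the normalized labels; rank association uses
Kendall tau-b (tie-corrected — labels contain near-ties during quiet
phases), validated against an O(n²) pair-counting oracle. The beta-power
baseline is the mean of squared 13–36 Hz band-passed samples over
(t − 2 s, t] per lead, correlated with the same labels as the model.
Group comparisons use Mann-Whitney U (α = 0.05) and, for paired
validation/test comparisons, Wilcoxon signed-rank with a Bonferroni
threshold of 0.025.

Band attribution filters the training visit's (already 8–100 Hz filtered)
LFP into six bands — delta-theta 0.5–8, alpha 8–13, low-beta 13–20,
high-beta 20–36, low-gamma 36–70, high-gamma 70–100.2 Hz (0.95 × Nyquist;
the 0.5 Hz lower edge keeps the first filter realizable) — rebuilds 5-s
windows on the label grid, and measures the variance of the scalar hooked
before the final ReLU; variances are normalized to ratios summing to 1.

## Limitations

* The variance-ratio probe feeds the network single-band inputs that are
  far weaker than its training distribution; parts of the head fall into
  dead-ReLU regions and the per-band output variance partly tracks the
  band's absolute input power. Attribution results are therefore a
  statement about the trained model's sensitivity, not about theoretical
  information content — and they are only interpretable when the spectrum
  has a realistic (beta-dominant) power distribution.
* With desk-scale learning rates the optimizer finds solutions whose
  single-band response patterns vary across seeds; attribution checks are
  majority-vote over seeds for this reason.
* The total-variation label is a reconstruction; other windowed-change
  statistics (e.g. range, RMS of differences) would change label scale
  and could change reported error magnitudes.
* Synthetic realism is qualitative: no published quantitative description
  of the force traces exists to calibrate against.
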