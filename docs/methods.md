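# Methods

`ecgpeaks` detects R-peaks (the dominant QRS deflection) in single-lead ECG
by combining a classical peak-enhancement front end with a 1-D
convolutional encoder-decoder that performs per-sample binary segmentation.
This note records the model, the defaults and their rationale, the
numerical choices, and what the synthetic benchmark does and does not show.

## Signal model and preprocessing

Records are resampled to 360 Hz by the Fourier method (spectrum zero-padded
or truncated, `scipy.signal.resample`), the rate the detector operates at.
Two filtering stages follow:

1. **Baseline-wander removal.** A 9-level DWT (Symlet 4) is taken, the
   level-9 approximation — the band below roughly 0.35 Hz at 360 Hz — is
   zeroed, and the signal is reconstructed. Measured attenuation of a pure
   drift tone: >99% at 0.05 Hz, ~95% at 0.1 Hz, ~78% at 0.2 Hz (the band
   edge is not sharp; leakage passes through the retained level-9 detail).
   The wavelet for this stage is a free choice; Symlet 4 is used for
   consistency with the enhancement stage.
2. **Powerline suppression.** A 4th-order Butterworth lowpass at 40 Hz,
   applied forward-backward (`filtfilt`) so the QRS apex is not displaced.
   The zero-phase double pass attenuates 60 Hz mains by well over 20 dB
   (measured in the test suite).

Two feature channels are derived from the filtered signal:

- the **level-4 stationary-wavelet-transform detail coefficient** (Symlet
  4). The SWT is undecimated (à-trous): per-level filters are the base
  decomposition pair upsampled by two from the previous stage, so every
  level keeps the signal length and the transform commutes with shifts.
  Level 4 at 360 Hz isolates roughly the 11-22 Hz band where QRS energy
  concentrates, suppressing P/T waves and drift;
- the **backward first difference** `d[n] = x[n] − x[n−1]` (leading zero),
  kept because the SWT magnitude slightly leads the true apex; the
  derivative's zero crossing pins the extremum itself.

Each channel is normalized by dividing by 16x its RMS (so channel RMS is
exactly 1/16 and excursions rarely exceed 1). Normalization statistics are
computed over the full waveform being featurized: a whole record at
inference time, the augmented 2048-sample window during training — the
window's own statistics, since augmentation deliberately varies amplitude.

Targets are binary masks with ones on the 150 ms window centered on each
annotated peak: at 360 Hz that is 54 samples, placed as `[p−27, p+27)`
(the peak sample sits in the right half-open block), clipped at record
boundaries; overlapping windows merge.

## Network

Input is a `(2048, 2)` feature window. All spatial convolutions have kernel
3 and ELU activations; every convolution is followed by batch normalization
and ELU, and each residual block starts with an ELU preactivation.

- **Encoder**: a conventional stride-2 stem convolution, then four residual
  stages. A stage applies three separable convolutions (depthwise kernel-3
  + pointwise), the third with stride 2, with a stride-2 pointwise
  convolution as shortcut. Five downsamplings in total: the bottleneck runs
  at 1/32 of the input. The compression is licensed by the ~200 ms cardiac
  refractory period — at stride 32 (89 ms) adjacent peaks still occupy
  distinct bottleneck frames.
- **ASPP**: parallel branches at dilations [1, 3, 6, 9] (the rate-1 branch
  is pointwise) plus a segment-pooling branch that averages bottleneck
  features over blocks corresponding to 2048 input samples and broadcasts
  them back — a time-series replacement for global average pooling, so
  pooled context stays local to a few heartbeats. Branches are concatenated
  and projected.
- **Decoder**: x8 linear upsampling, concatenation with a
  pointwise-reduced skip from the stride-4 encoder stage, two separable
  convolutions, x4 upsampling, a pointwise head and a sigmoid: per-sample
  peak probabilities at input resolution.

Channel widths are declared defaults, not extracted from any reference:
stem 16, stages (32, 64, 128, 256), ASPP 128, skip reduction 32, decoder
64. The decoder is deliberately narrow: a binary mask needs far less
capacity than the encoder's feature extraction, and the decoder operates at
the longest (most expensive) resolutions. Upsampling is parameter-free
linear interpolation. With these defaults the model has ~560k parameters;
swapping separable for conventional convolutions (`separable=False`) more
than doubles that, which is the point of the separable design.

The network, its gradients, and the Adam optimizer are implemented in numpy
inside `ecgpeaks.nn` — a small reverse-mode autodiff with exactly the
primitives this architecture needs. The backward pass is verified against
central finite differences on a float64 configuration in the test suite.

## Training

Each epoch draws fresh augmented windows (default: total training samples /
2048; the reference benchmark uses 2000), optimized with dice loss
(`1 − (2Σpt + s)/(Σp + Σt + s)`, smooth `s = 1`) and Adam (lr 1e-3, batch
128, at most 100 epochs by default). Dice loss suits the class balance:
ones cover only ~10-15% of samples at normal heart rates.

Augmentation has two steps, applied to a random 2048-sample crop of the
filtered waveform:

1. **Shape**: time-rescaling by a factor drawn log-uniform from
   [0.8, 1.25] (a symmetric-in-log heart-rate change; peaks are remapped
   and the window re-cropped/padded), additive Gaussian noise with sigma up
   to amplitude/30 (so 3-sigma excursions stay within ±10% of the waveform
   amplitude), and multiplication by a slow sinusoid `1 + a·sin(2πft+φ)`
   with depth `a ≤ 0.5` (range [0.5, 1.5]), frequency log-uniform in
   [0.05, 0.5] Hz. Gaussian noise is applied before modulation.
   "Amplitude" throughout is the 99.9th minus the 0.1th percentile.
2. **Noise injection** (probability 0.5): random window-length slices of
   baseline-wander, muscle-artifact and electrode-motion templates — each
   included with probability 1/2, at least one forced — summed, normalized
   to unit amplitude, and added scaled by `s·A(x)`, where `A(x)` is the
   window amplitude and `s = |N(0, noise_sd)|` rejection-truncated at 2.
   `noise_sd` defaults to 0.05; raising it (e.g. 0.5) trades clean-signal
   performance for noise robustness.

The window is then sign-flipped and/or time-reversed (two independent 50%
coins) before feature extraction, so the model also learns inverted and
mirrored morphologies. Every draw is reproducible from the generator state.

After each epoch the un-augmented records are scored with the full
detection pipeline (150 ms smoothing) and pooled F1 is monitored: the best
checkpoint is kept, improvement means an increase > 1e-5, early stopping
fires after 10 non-improving epochs (default), and the learning rate halves
after 5 (declared choices; only batch size, epoch cap and patience follow
the reference protocol).

## Peak localization

The probability sequence is smoothed with a centered moving average — 150 ms
for internal validation, 75 ms for testing (the shorter window recovers
sensitivity on unseen data); window lengths round to the nearest odd sample
count (55 and 27 at 360 Hz), edges are zero-padded. Local maxima above 0.5
(plateaus collapse to their floored center) are then kept greedily in
descending probability subject to a 200 ms minimum separation (72 samples at
360 Hz) — the cardiac refractory period.

Full records are processed in 2048-sample windows at stride 1024; each
window contributes its central 1024 samples (the first and last also keep
their outer halves), which avoids convolution-padding artifacts at window
edges. Records shorter than one window are symmetric-padded and trimmed.

## Evaluation

A detection matches a reference beat if within 150 ms. Scoring uses the
maximum-cardinality one-to-one matching between the two sorted index lists,
computed exactly: the problem splits at gaps larger than the tolerance into
small independent components, each solved by an LCS-style dynamic program.
This makes scores detector-best-case and deterministic (the matching
procedure is otherwise a free choice, and greedy variants are not always
optimal). Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP), F1 their harmonic
mean; degenerate conventions: sensitivity 1 with no reference beats, PPV 1
with no detections, F1 0 when both components vanish while beats exist.
Counts pool across records before metrics are computed. Regions marked for
exclusion (e.g. ventricular flutter in annotated databases) drop both
references and detections before matching.

## Synthetic data

The generator renders each beat as Gaussian bumps (P, Q, R, S, T) at
textbook lead-II offsets and amplitudes, with per-beat amplitude jitter,
occasional inverted or widened P-less (ectopic-like) beats, RR intervals
~ Normal(60/HR, jitter) truncated above 0.25 s (consistent with the 200 ms
refractory assumption), and a small white-noise floor. The exact R indices
used for rendering are the ground truth. Noise templates emulate the three
classic noise-stress-test classes: sub-0.5 Hz sinusoids with drifting phase
(baseline wander), 20-100 Hz bandpassed Gaussian noise (muscle), and
piecewise baseline steps plus exponential-decay spikes at Poisson times
(electrode motion).

What this emulates — and what it does not: morphology regularity is far
higher than in arrhythmia databases; there are no rhythm changes, conduction
abnormalities, pathological ST/T morphology, or recording dropouts. Passing
the synthetic benchmark therefore demonstrates that the pipeline wiring,
learning dynamics, localization and scoring are correct and that the model
generalizes across the generator's amplitude/rate/polarity/noise variation —
it does not certify clinical performance, which requires the standard
annotated databases (supported via the WFDB reader but never required).

## Reference benchmark

`ecgpeaks.benchmarks.synthetic_recovery` trains the default model on 20 min
of synthetic ECG (~2000 windows/epoch, at most 12 epochs, early-stopping
patience 3 — internal validation saturates within a few epochs at these
sizes) once with `noise_sd = 0.05` and once with 0.5, then scores a held-out
5-min record clean and with electrode-motion noise added at the waveform's
own amplitude (scale 1.0). Expected behavior: near-perfect clean F1, high
noisy F1, and the strongly-augmented model no worse under noise than the
default one.

## Numerical choices and edge cases

- SWT inputs are padded symmetrically at the tail to a multiple of 2^4 and
  trimmed (the transform itself is periodic; a `periodic` mode without
  padding is exposed and is shift-equivariant to 1 ulp).
- Records shorter than 2^9 samples are symmetrically padded for the
  baseline DWT; all-zero waveforms are rejected at normalization
  (degenerate records).
- Annotation index remapping after resampling rounds half-even and merges
  collisions keeping the first beat; it never reorders.
- Batch-norm statistics are frozen (running averages, momentum 0.1) at
  inference; training history is bit-reproducible for a fixed seed on one
  thread.
- Detection ties (equal probability) break toward the earlier index.
- Metrics are reported rounded half-even to 4 decimals.

## Known limitations

- The numpy network trains at CPU memory-bandwidth speed; the reference
  benchmark sizes were chosen so the full loop runs in minutes, not hours.
  Larger corpora want a GPU port of the same architecture.
- The 0.2 Hz edge of baseline removal passes ~22% of drift amplitude (see
  above); drift between 0.2-0.35 Hz is only partially removed.
- Multi-lead fusion, beat classification, rhythm analysis and
  ventricular-flutter handling are out of scope; one channel is selected
  and flutter regions are handled only via the generic exclusion interface.
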