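# Methods

## Signal model

A depth sensor observing a sleeper's chest reports, inside a rectangular
region of interest (ROI), distances that decrease as the chest rises. The
package models the chest displacement as

```
w(t) = A · e(t) · sin(2π f t) + drift(t),
```

with breathing rate `f` (default 0.28 Hz ≈ 17 breaths/min; adults during
sleep breathe at 0.26–0.33 Hz, the elderly at 0.16–0.5 Hz), amplitude `A`
in millimetres, and an event envelope `e(t)` equal to 1 outside apnea
events and to the event's *attenuation* (fraction of effort remaining)
inside. Central apnea is rendered as a near-constant small envelope
(default attenuation 0.1), obstructive apnea as attenuated effort carrying
an additional slow 0.05 Hz modulation — below the band-pass region, so the
modulation itself cannot masquerade as breathing — and a mixed event
behaves centrally in its first half and obstructively in its second.
Clinical event statistics motivate the default simulated durations
(12–37 s, within the 5–44.5 s envelope of annotated events). Optional
posture drift is a Gaussian random walk (`drift_sd` mm/√s, default 0).

There is no firm reference value for chest amplitude in depth units; the default
`A = 6 mm` sits in the plausible 4–10 mm range and matches the distance
error scale of the worst sensors (6 mm Kinect v2, 3 mm R200), so
quantization to whole millimetres is a real effect the pipeline must
survive. Rendering writes `baseline − w(t)` plus per-pixel Gaussian noise
into uint16 frames (1 unit = 1 mm), clipped and rounded; the ROI mean then
enjoys a `1/√(R·S)` noise reduction, which is why frame size in simulations
can be small (24×24 with a 16×16 ROI) without changing the statistics that
matter.

Frame timestamps follow one of three jitter models per sensor profile:
`none` (uniform grid), `uniform` (intervals jittered symmetrically, bounded
so the instantaneous FPS stays inside the sensor's declared range), and
`heavy_tail` (intervals near the maximal frame rate with occasional gap
multipliers drawn from {4, 6, 8, 10}, their probability chosen so the mean
FPS matches the declared mean — the behaviour of a sensor that time-shares
its depth pipeline with skeletal tracking). Declared profiles: Kinect v2
3–29 FPS mean 20 (heavy-tailed), SR300 25–45/35, R200 25–43/33, D415
27–33/30, D435 25–37/30 (uniform).

What the generator does **not** emulate: body and blanket geometry, posture
changes, sensor-specific artefacts (undefined depth pixels, rolling-shutter
effects), and real apnea physiology beyond an amplitude envelope. Passing
tests on synthetic data therefore demonstrate the signal-processing and
classification machinery under controlled conditions, not clinical
performance.

## Extraction chain

1. **Frame differencing.** `d(n)` is the ROI mean of `D_{n+1} − D_n`;
   each difference sample carries the timestamp of the later frame.
2. **FIR band-pass**, cutoffs 0.01–1 Hz. The filter is a Hamming windowed
   sinc of odd length `M` (default 1001) designed at the record's mean
   frame rate; coefficients are shifted by their mean so `Σ b(k) = 0`
   exactly — DC rejection independent of `M`. At `M = 1001` the transition
   band (~0.1 Hz at 30 FPS) is far wider than the 0.01 Hz low edge; the
   exact zero-sum shift is what actually guarantees mean removal. Filtering
   runs at the native (irregular) rate treating samples as uniform at the
   mean FPS — accurate for the mild jitter of these sensors; a flag moves
   filtering after resampling instead. Convolution uses reflective padding
   of (M−1)/2 samples on each side so the linear-phase group delay is
   cancelled and output samples stay aligned with their timestamps (a
   purely causal variant is available); at 30 FPS the kernel spans ~30 s,
   so some ringing of neighbouring breathing into event interiors is
   inherent to this operating point.
3. **Savitzky–Golay smoothing** (second order, window 11 samples, optional
   and on by default), with polynomial edge fitting so exact quadratics are
   reproduced everywhere.
4. **Cubic-spline resampling** onto `t₀, t₀+0.1 s, …` (10 Hz, the PSG
   breathing-channel rate); the spline is never extrapolated past the last
   timestamp.

## Features and classifier

Windows of 10 s step at 0.1 s: 10 s covers ≥ 2 breath cycles at the slowest
adult rate, and the 0.1 s step puts one window centre on every point of the
10 Hz label grid. Each window yields its **dominant frequency** (argmax of
the Hann-tapered, ≥8× zero-padded amplitude spectrum restricted to
0.05–1 Hz — above drift, below the filter's high cutoff; ties break toward
the lower frequency) and its **sample standard deviation** (n−1
normalisation). Every grid sample takes the label of the window centred on
it; the first and last half-windows inherit the nearest centre's label.

The classifier is a two-neuron competitive layer trained without a teacher:
per presented vector the neuron nearest in Euclidean distance wins and
moves toward it by a linearly decaying learning rate. Numerical choices
that matter:

- **Z-scoring** of features before training, with the scaling accumulated
  in a canonical (sorted) row order so training is bit-identical under any
  permutation of the input rows.
- **Learning rate 0.01 → 0.001** over 1000 epochs. Online winner-take-all
  updates are unstable at rates an order of magnitude larger when the
  feature distribution is heavy-tailed: a single far outlier then drags a
  prototype out of the data bulk in a few presentations. 0.01 is the
  classical Kohonen-layer setting and converges well within 1000 epochs.
- **Initialization from distinct data points restricted to the bulk**
  (|z| ≤ 3 per feature, with a fallback when the data are degenerate): a
  prototype seeded on a rare outlier wins only outliers and never learns
  the main structure.
- **Four seeded restarts, keeping the lowest mean quantization error** —
  the analogue of k-means `n_init`. Degenerate local optima (a prototype
  settling on a tight minority cluster along the dominant-frequency axis)
  carry measurably higher quantization error than the breathing/apnea
  split, so error selection is self-correcting.
- Ties in the winner search go to the lower neuron index; training is
  deterministic given the config seed.

Clusters are anonymous, so a naming step follows: by default the cluster
whose centroid has the smaller standard-deviation feature *in original
units* is apnea (breathing effort collapses during an event); a supervised
mode assigns by majority vote against reference labels instead. The
K-means baseline is Lloyd's algorithm from a seeded sample init, run on
raw (unscaled) features by default and reporting its per-iteration
objective.

A known limitation of the two-feature Euclidean geometry: a window whose
dominant frequency lies far outside the training distribution (e.g. white
noise never seen during training) is routed by the — there meaningless —
frequency axis rather than by its amplitude. Within a record this does not
arise, because the classifier is trained on segments of the same record;
silence the pipeline itself produces classifies as apnea.

## Evaluation

Training segments are one annotated event plus 25 s of margin each side,
clipped to the record; events whose neighbour starts or ends within 25 s
are excluded from training (their margins would not be clean breathing)
but remain available for event-level evaluation. Margins are labelled
normal in the truth track; in real specialist annotations the surrounding
signal may contain unmarked events, a caveat that applies to any such
ground-truth construction.

Metrics follow the standard confusion-matrix definitions with apnea as the
positive class, reported in percent at one decimal; a metric whose
denominator is zero is reported as undefined (None), never coerced to 0.
Both algebraic F1 forms (harmonic mean of precision and sensitivity;
2TP/(2TP+FP+FN)) agree to numerical precision by construction. Event
detection merges apnea runs separated by ≤ 2 s, discards runs shorter than
5 s (the minimum length of real annotated events), and counts an annotated
event as detected when any predicted run overlaps it; predicted runs per
recorded hour give the clinical events-per-hour index. Validation uses
five seeded random 70/30 splits at segment granularity — the literal
"70% of segments for training" reading, since a 5-fold partition would
imply 80/20 — and summarises each metric as mean ± sd.

## Benchmark operating point and problem sizes

The packaged benchmark generates 20 records of 15 minutes at 0.25 Hz with
4–5 central/obstructive events of 12–37 s per record, event attenuation at
most 0.2, per-pixel noise 0.2 × amplitude, and the R200 frame-rate profile;
records are rendered as 24×24-pixel frames (16×16 ROI). At this operating
point the pipeline detects 100% of annotated events across every base seed
tried, with pooled per-sample F1 of 90–92% for the competitive net —
consistently, if modestly, above the unscaled-feature K-means baseline
(~85–91%). On clinical PSG-derived features, unscaled K-means can collapse
entirely when one feature's numeric scale dwarfs the other's; the synthetic
extraction yields comparable scales for the two features, so here the
baseline degrades only modestly. Sensitivity is bounded in the low 90s by
the soft transitions at event boundaries, where a 10-s window straddles
breathing and silence — the dominant source of false classifications at
every operating point tried.
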