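# Methods

## Pipeline model

`fincam` treats fish monitoring as a three-stage reduction of a video
stream:

1. **Thinning** converts continuous footage into a sparse, regular sample
   of frames. Detection therefore happens at sample resolution: a fish
   visible for shorter than one thinning interval can fall between samples
   and be missed, and a shorter interval raises detection probability at
   the cost of more images to score and review. The interval is a
   first-class survey parameter: changing it mid-study changes detection
   probability and must be accounted for downstream.
2. **Scoring** assigns each sampled frame an independent probability of
   containing a fish. No temporal smoothing is applied — each frame is
   scored on its own, and temporal structure enters only through the event
   algorithm.
3. **Event segmentation** interprets runs of adjacent above-threshold
   samples within one video file as one continuous fish observation, and
   materialises each as a buffered clip. The buffer (default 20 s each
   side) exists because the thinned sample that triggered detection is a
   point probe of a longer pass; padding recovers the surrounding footage
   where the fish is likely still visible and possibly sharper.

## Frame-index bookkeeping

All frame and sample indices are 1-based. Sample *i* is anchored at the
*first* frame of its interval: `f(i) = (i − 1)·round(fps·interval_s) + 1`.
Anchoring at the interval start (rather than midpoint or end) is a
convention choice; different extraction toolchains legitimately differ by
a sub-interval offset, so the convention is fixed, documented, and used
consistently for both extraction and the reverse mapping from predictions
to frames. Non-integer `fps·interval_s` products are rounded to the
nearest integer stride so frame numbers stay integral and strictly
monotone; for the common 20 fps / 20 s operating point the stride is
exactly 400.

Chronological order across files is derived from a configurable filename
timestamp pattern (default `YYYYMMDD[_-]HHMMSS`), with lexicographic path
order as tie-break. Files without a parseable timestamp sort before dated
ones, by path.

## Media backends

Probing (fps, frame count), frame decoding and clip writing go through
pluggable container backends:

- **ImageJ-TIFF stacks** (`tifffile`) — lossless, exact fps metadata,
  frame-exact cuts; the default container for synthetic work and tests.
- **GIF** (Pillow) — frame-exact; fps is limited to what an integer
  per-frame millisecond duration can express.
- **ffmpeg/ffprobe binaries** — MP4/MKV/AVI/H.264 field footage. Probing
  prefers the container's exact frame count and falls back to
  `round(duration × fps)` with an `frame_count_estimated` flag when the
  container does not carry one. Cutting re-encodes by default
  (frame-accurate `select` filter); stream-copy is available as a fast
  option with documented keyframe-snap imprecision of up to one GOP.
  Requesting these formats without the binaries installed raises a
  capability error; the in-process backends are unaffected.

Extracted stills are PNG by default (lossless); JPEG is available.

## Classifier

The training recipe is fixed across backends: a frozen feature extractor,
then a trainable head — dense(units, ReLU) → dropout → dense(2, softmax) —
optimised with categorical cross-entropy and Adam (learning rate from the
spec) in mini-batches of 32 for 3 epochs, on a seeded stratified 80/20
train/validation split. The hyper-parameter grid is the full cross of
learning rate {1e-2, 1e-3} × dropout {0.2, 0.3} × dense units {256, 1024}
(8 configurations); grid search keeps the highest validation accuracy,
ties resolved toward the earlier grid position, and individual failed fits
are logged and skipped rather than aborting the search.

Two backends provide the frozen extractor:

- **`pooled`** (default, pure numpy): 32×32 grayscale downscale, then 8×8
  block-wise mean *and* max intensities (128 features, scaled to [0, 1]
  and standardised to the training set). The max channel keeps a small
  bright object visible where block averaging would dilute it. Adam,
  dropout and the softmax head are implemented directly; everything is
  seeded. This backend trains in well under a second on hundreds of
  images and carries the full pipeline without any deep-learning
  dependency.
- **`xception`** (optional `dl` extra): ImageNet-pretrained Xception at
  its native 299×299 input, bilinear resize without aspect preservation,
  backbone frozen, with the same head on its 2048-wide pooled features.
  Per-image preprocessing follows the backbone's expected input range.
  Training determinism across hardware is not promised.

Class imbalance is left unweighted by default. Predictions are the softmax
mass on the fish class; unreadable images are recorded as missing (NaN)
and logged, never silently dropped, and a missing score breaks event
adjacency rather than fabricating continuity. A CSV predictor replays
stored scores bit-exactly (round-trip float parsing), so downstream stages
are re-runnable with no model present. The mock predictor — the scaled
fraction of pixels above a brightness threshold — is a pure function of
image bytes, used for demos and plumbing tests.

## Event algorithm details

- Threshold comparison is inclusive (`p ≥ threshold`).
- Grouping never crosses a file boundary, and group numbering restarts per
  video.
- Duplicate (video, sample) pairs and out-of-order streams are errors, not
  repairs: ordering is the producer's contract.
- The buffer is expressed in seconds and converted through each video's
  own fps, so mixed-frame-rate batches buffer by equal *time*, not equal
  frame counts.
- Buffered windows of distinct events may overlap; they are not merged by
  default (each observation stays its own clip), with an opt-in
  `merge_overlaps` pass for workflows that prefer fused clips.

## Reporting

Probabilities are multiplied by 100 and rounded to the nearest whole
percent — halves away from zero, applied to the floating-point value of
`100·p` — giving 101 exhaustive, disjoint bins. The frequency table is
dense (zero cells retained) in machine-readable output and compressed to
nonzero rows in the rendered text. The review queue takes every image at
or above a percent cutoff (default 3 %), ordered by percent descending
then chronologically; verdicts persist to a CSV sidecar and can be folded
back into the training folders later. A packaged long-format CSV of
per-date percent-bin counts from a six-day salmon monitoring campaign
(Mörrumsån, 2023-07-22 … 27; 17,296 thinned images) serves as a realistic
fixture and scale reference.

## Synthetic data

The generator emulates fixed underwater surveillance: a static gray
stream-bed with a mild horizontal illumination ramp, per-pixel Gaussian
noise (default σ = 12 gray levels) standing in for turbidity, a
whole-frame luminance swing that grows quadratically with the noise level
(emulating white-water glare episodes; negligible at the default), and —
during configured presence windows — a bright ellipse (intensity 230)
crossing the field of view with a sinusoidal sway. Scenes default to 20
fps, the frame rate the pipeline's frame arithmetic is usually run at, at
a 160×90 working resolution: the event algorithm, frame maths and clip
writing are resolution-independent, so tests gain nothing from rendering
at the 4K of field recordings. Ground truth is stored at frame resolution
(frame *f* contains the object iff its timestamp lies in the half-open
presence window), so thinning-interval effects on detection are directly
measurable.

Probability streams bypass rendering entirely: background scores draw
uniformly from a sub-threshold band (default [0, 0.30]) and planted runs
sit at a fixed super-threshold level (default 0.9), with run layouts
validated to be sorted, in-range, and separated by at least one sample so
the expected event list is exact by construction.

What the synthetic fixtures do **not** emulate: motion blur, bubbles and
debris, partial or blurry fish, compression artefacts, lighting change
over a day, or multiple simultaneous fish. Passing tests therefore
demonstrate that the plumbing, index bookkeeping and the event algorithm
are correct — not that any classifier reaches field accuracy on real
water; the ≈93 % validation-accuracy regime reported for real footage of
this kind is only attainable (and only meaningful) on real labelled data.

## Numerical and degenerate-input choices

- An interval longer than the video yields exactly one sample (frame 1),
  not an error.
- A single-frame video is valid everywhere (probe, thin, cut).
- Zero events is a success: empty manifest, exit 0.
- Per-event clip-write failures are recorded in the segment manifest's
  `error` column and do not stop remaining events.
- `round()` (banker's at .5 in Python) is used for the frame stride and
  buffer conversion; the operating points of interest (20 fps with 2-s,
  20-s intervals/buffers) are exact integers, so the tie rule never
  matters there. Percent binning uses half-away-from-zero explicitly.
- Softmax is computed with max-subtraction; Adam uses bias correction and
  ε = 1e-7.

## Known limitations

- Stream-copy cuts snap to keyframes; frame-exact guarantees hold only in
  re-encode mode (and always for TIFF/GIF).
- The pooled backend is a high-contrast-object classifier; it is not
  expected to transfer to real footage, where the Xception backend (or any
  trained model exposed through the predictor contract) should be used.
- Writing MP4 output requires the ffmpeg binary; array-to-MP4 encoding is
  not provided in-process.
- The review queue supports recording verdicts but no inter-rater
  reconciliation or automated verdicts.
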