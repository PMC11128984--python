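# fincam

Camera-based monitoring of trout and salmon in small streams produces far
more surveillance video than anyone can watch. `fincam` automates the
sorting step: it thins each video to one frame per fixed time interval,
scores every frame with a two-class fish / no-fish classifier, groups
adjacent above-threshold frames into *detection events*, and cuts a
buffered, frame-accurate video clip of each event — short segments in which
a fish is visible, ready for manual individual identification from natural
markings (and from there for capture–recapture or relative-abundance
modelling). It also produces the percent-probability frequency table and
manual-review queue used to evaluate the classifier.

It is written for fisheries researchers and managers running cheap
NVR + underwater IP-camera setups, but any fixed-camera monitoring workload
with the same shape (long videos, rare events, per-frame scores) fits.

## The event algorithm

For a batch of videos in chronological order, with frames indexed 1-based:

- **Thinning.** One frame every `interval_s` seconds (default 20 s).
  Sample *i* of a video maps back to source frame
  `f(i) = (i − 1) · round(fps · interval_s) + 1`, so a video with *N* frames
  yields `⌊(N − 1)/round(fps · interval_s)⌋ + 1` samples.
- **Scoring.** A classifier assigns each sampled frame a probability
  `p ∈ [0, 1]` of containing a fish (softmax mass on the fish class).
- **Filtering.** Keep samples with `p ≥ threshold` (default 0.5).
- **Grouping.** Split by video file, then group maximal runs of consecutive
  sample indices (a gap > 1 breaks adjacency) — each run is one detection
  event, spanning frames `[min f(i), max f(i)]` of its members.
- **Buffering.** Pad both ends by `round(buffer_s · fps)` frames (default
  20 s, i.e. 400 frames at 20 fps), clamping to `[1, N]`, and cut that
  range as one clip.

The classifier recipe is transfer learning: a frozen ImageNet-pretrained
Xception backbone with a trainable head (global average pooling →
dense-ReLU → dropout → dense-2 softmax), categorical cross-entropy, Adam,
batch 32, 3 epochs, grid-searched over learning rate {1e-2, 1e-3} × dropout
{0.2, 0.3} × dense units {256, 1024} (8 models). That backend needs the
optional `dl` extra; the default trainable backend implements the same head
and optimisation over fixed pooled-intensity features in pure numpy, and
the pipeline also runs with a deterministic mock predictor or stored
per-frame scores (CSV), so no deep-learning install is required.

## Worked example

Simulate a 60-s, 20-fps recording with fish present during 10–14 s and
40–46 s, then run the full workflow:

```sh
fincam simulate --kind scene --out 20230726_050000_cam1.tif \
    --duration 60 --fps 20 --fish-interval 10 14 --fish-interval 40 46 --seed 1
fincam thin 20230726_050000_cam1.tif --interval 2 --out-dir stills --manifest frames.csv
fincam predict frames.csv --predictor mock --out preds.csv
fincam segment preds.csv --out-dir clips
fincam report preds.csv --out-prefix rep
```

which prints:

```
1200 frames -> 20230726_050000_cam1.tif (truth: 20230726_050000_cam1.truth.csv)
30 samples from 1 videos -> frames.csv
30 predictions -> preds.csv
2 events -> clips/segments.csv
30 predictions tabulated over 1 dates; 5 images queued for review (>= 3%)
```

The segment manifest (`clips/segments.csv`) shows the two recovered events
with their raw and buffered frame bounds — e.g. the first event spans
frames 201–241 (samples at 10 s and 12 s), buffered by 400 frames to 1–641
and clamped at the video start:

```
video_path,group_id,start_frame,end_frame,buffered_start,buffered_end,n_samples,clip_path,error
20230726_050000_cam1.tif,1,201,241,1,641,2,clips/20230726_050000_cam1_g1_f1-641.tif,
20230726_050000_cam1.tif,2,801,881,401,1200,3,clips/20230726_050000_cam1_g2_f401-1200.tif,
```

and the rendered frequency table (`rep_table.txt`) counts the 30 scored
frames per rounded percent bin for the recording date:

```
         2023-07-26
percent
0                25
84                3
87                2
total    30   (grand total 30)
```

The five frames at ≥ 3 % land in `rep_review.csv`, highest probability
first, ready for manual verdicts.

The same stages are available as library functions (`fincam.thin_batch`,
`fincam.predict_batch`, `fincam.run_segmentation`,
`fincam.build_probability_table`, ...) and every stage reads/writes plain
CSV, so segmentation and reporting can be re-run from stored scores without
any classifier.

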