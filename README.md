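# embryostage

Morphokinetic stage annotation for embryo time-lapse videos: frame-level
stage classifiers (image-only and image+time fused), a two-stage
postprocessing algorithm that denoises per-frame predictions, and
extraction of exact stage-transition timings with quantile error
analysis. Everything is exercisable end to end on synthetic data — no
clinical dataset is required.

## What's inside

| Module | Purpose |
| --- | --- |
| `embryostage.ontology` | The 17-class stage label set (tPB2 … tHB, Empty), ordering, parsing |
| `embryostage.time_encoding` | One-hot two-hour-window encoding of minutes since fertilisation (length 84) |
| `embryostage.postprocess` | Confidence-threshold substitution + run-grouping interruption removal |
| `embryostage.timings` | Transition-event extraction, signed timing errors, percentile summaries |
| `embryostage.metrics` | Confusion matrix (row %), accuracy, macro precision/recall/F1, inverse-frequency class weights |
| `embryostage.nn` | Numpy-backed classifiers (tiny + reference-scale conv backbones, two-head attention fusion), CLAHE preprocessing, augmentation, Adam training with plateau schedule |
| `embryostage.synthetic` | Ground-truth timelines, stage-coded rendered frames, noisy prediction simulation, dataset generation with 70/10/20 video-level splits |
| `embryostage.io` / `embryostage.cli` | CSV/JSON interchange formats and the command-line interface |

The smoother works in two stages: frames whose top-class probability is
not above 0.8 inherit the most recent confident label; the label
sequence is then partitioned into runs by cumulative change counting,
and any run of a foreign class falling strictly inside a class's span of
runs is relabelled to that class, iterated to a fixpoint. Genuine,
persistent stage reversions (reverse cleavage) are preserved — the
output is not forced to be monotone.

The classifier stack runs on a small in-repo reverse-mode autograd
(numpy only), so training and the two-head gradient-flow checks work in
a minimal environment without a deep-learning framework.

## CLI

```sh
# synthetic dataset with annotations + 70/10/20 split manifest
embryostage simulate --n-videos 20 --out data/ --seed 1

# train / predict (tiny backbone by default; YAML config optional)
embryostage train --data data/ --out model.npz --seed 1 --epochs 10
embryostage predict --model model.npz --data data/ --out pred.csv

# denoise per-frame predictions, extract timings, evaluate frames
embryostage smooth --predictions pred.csv --threshold 0.8 --out final.csv
embryostage timings --final final.csv --truth data/annotations.csv --summary summary.csv
embryostage evaluate --pred pred.csv --truth data/annotations.csv --out metrics.json

# debugging helper
embryostage encode-time --minutes 150
```

## Data formats

- `annotations.csv`: `video_id,frame_index,time_minutes,label`
- predictions CSV: `video_id,frame_index,time_minutes,p_<label>` × 17
- final labels CSV: `video_id,frame_index,time_minutes,label_raw,label_final`
- events CSV: `video_id,stage,time_hours`
- timing summary CSV: rows `count, mean, std, 25% … 99%`, one column per stage
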