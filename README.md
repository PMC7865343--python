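# gaitphase

Five-phase gait segmentation from multi-IMU time series.

The package implements a complete, self-contained pipeline for frame-level
gait-phase recognition:

1. **`gaitphase.synthetic`** — generates coupled IMU + pressure-plate
   recordings (10 sensor units x 7 channels at 120 Hz, a two-peaked stance
   force curve with zero-force swing) with exact ground-truth phase labels,
   per-subject gait variability and configurable noise.
2. **`gaitphase.labeling`** — synchronizes the streams on their trigger
   frames and converts the total-force curve into per-frame labels
   {IC, LR, MS, TS, SW} using the local extrema of each step's force curve
   (contact -> stretched initial contact -> first peak -> valley -> toe-off).
3. **`gaitphase.windowing`** — sliding windows (default 50 frames x 70
   channels, shift 1), device/measurement channel orderings, chunking into
   fixed-length sequences, and leave-one-subject-out train/val/test splits
   (66/34 with 10% of train for validation).
4. **`gaitphase.nn`** — the classifier: 6 zero-padded convolutions
   (6x6 then 3x3 kernels, max-pooling after every second layer), per-window
   features flattened into a 2-layer LSTM over the window sequence, then a
   dense head (1024 -> 256 -> 5 softmax at full scale). Implemented in pure
   NumPy (explicit backprop, Adam, Glorot init, dropout 0.2, L2 on conv
   weights) because the runtime environment ships no deep-learning
   framework; all gradients are validated against finite differences in the
   test suite.
5. **`gaitphase.evaluation`** — confusion matrices, transition-tolerant
   accuracy, per-misprediction time offsets (per-frame or per-event),
   softmax-certainty rejection reports, LOOCV statistics, and activation
   heatmaps over the last convolutional layer.
6. **`gaitphase.cli` / `gaitphase.experiments`** — command-line drivers,
   JSON configuration, manifests, and greedy one-parameter sweeps
   (LSTM size, channel order, per-location sensor subsets).

## CLI

All verbs read a single JSON config (unknown keys are rejected) and write a
`manifest.json` with the config echo, seeds and library versions.

```sh
gaitphase simulate config.json data/          # one directory per subject
gaitphase label    config.json data/          # events.json + labels_pred.csv
gaitphase windows  config.json data/ out.h5   # window tensors as HDF5
gaitphase train    config.json data/ run/     # checkpoint + history + reports
gaitphase evaluate config.json data/ run/model out/
gaitphase loocv    config.json data/ loocv.json
gaitphase sweep    config.json data/ sweep.csv
```

Exit codes: 0 ok, 1 usage error, 2 data/config error.

Minimal config example:

```json
{
  "synthetic": {"n_subjects": 11, "duration_s": 20.0, "seed": 42},
  "windowing": {"window_len": 30, "shift": 4, "seq_len": 48},
  "labeling": {"ic_stretch": 10},
  "model": {"conv_filters": [6, 6, 12, 12, 24, 24], "dense_units": [64, 32]},
  "train": {"epochs": 10, "batch_size": 4, "seed": 0},
  "split": {"unseen_subject": "subject_10", "seed": 0}
}
```

`model.lstm_units` defaults to the number of windows per sequence (the best
value in the size sweep); set it explicitly to override.

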