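"""Evaluation: confusion matrices, transition-tolerant accuracy,
misprediction offsets, certainty-based rejection, LOOCV statistics, and
conv-activation heatmaps.

Errors of this classifier cluster at phase transitions, so plain accuracy is
complemented by a tolerance variant: a prediction at frame ``t`` counts
correct when the true stream holds the predicted class anywhere within
``tol`` frames of ``t`` (symmetric).  Offsets of mispredictions are measured
the same way — distance to the nearest frame whose true class matches the
prediction — and reported in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from gaitphase.errors import DataError
from gaitphase.nn.network import PredictionSet
from gaitphase.types import N_PHASES

__all__ = [
    "EvalReport",
    "RejectionReport",
    "activation_heatmap",
    "certainty",
    "certainty_stats",
    "confusion_and_accuracy",
    "expected_transition_error_pct",
    "frame_ms",
    "frame_ms_label",
    "loocv",
    "loocv_summary",
    "misprediction_offsets",
    "reject_by_certainty",
    "tolerance_accuracy",
]


def frame_ms(rate_hz: float) -> float:
    """Duration of one frame in milliseconds (8.33 ms at 120 Hz)."""
    return 1000.0 / rate_hz


def frame_ms_label(rate_hz: float) -> int:
    """The rounded per-frame label used in figures (8 ms at 120 Hz)."""
    return int(round(frame_ms(rate_hz)))


def expected_transition_error_pct(
    n_transitions: int = 5, cycle_frames: int = 120, miss_frames: float = 1.0
) -> float:
    """Misclassification percentage when every transition in a cycle is
    missed by ``miss_frames`` frames: 100 * n * miss / cycle_frames."""
    return 100.0 * n_transitions * miss_frames / cycle_frames


def certainty(z: np.ndarray) -> np.ndarray:
    """Softmax of a logit vector (or [N, K] rows), stabilized by max-shift."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise DataError("empty logit vector")
    if not np.all(np.isfinite(z)):
        raise DataError("logits must be finite")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class EvalReport:
    confusion: np.ndarray  # [K, K], rows = true, cols = predicted
    accuracy: float
    tolerance_accuracy: dict[int, float] = field(default_factory=dict)
    offsets_ms: np.ndarray | None = None
    unmatched_frames: np.ndarray | None = None  # predicted class absent in truth
    certainty_correct: dict | None = None
    certainty_wrong: dict | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "tolerance_accuracy": {str(k): v for k, v in self.tolerance_accuracy.items()},
            "offsets_ms": None if self.offsets_ms is None else self.offsets_ms.tolist(),
            "unmatched_frames": None
            if self.unmatched_frames is None
            else self.unmatched_frames.tolist(),
            "certainty_correct": self.certainty_correct,
            "certainty_wrong": self.certainty_wrong,
        }


@dataclass
class RejectionReport:
    threshold: float
    accuracy_retained: float | None  # None when everything was rejected
    n_total: int
    n_unknown: int
    n_correct_to_unknown: int
    n_wrong_to_unknown: int
    frac_unknown: float
    frac_correct_to_unknown: float
    frac_wrong_to_unknown: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def confusion_and_accuracy(pred: PredictionSet, n_classes: int = N_PHASES) -> EvalReport:
    """Count matrix by (true, predicted) plus plain accuracy."""
    if pred.true is None:
        raise DataError("PredictionSet has no ground-truth labels")
    t = np.asarray(pred.true)
    p = np.asarray(pred.pred)
    if t.shape != p.shape:
        raise DataError(f"length mismatch: true {t.shape} vs pred {p.shape}")
    if t.size == 0:
        raise DataError("empty prediction set")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (t, p), 1)
    accuracy = float(np.trace(confusion) / confusion.sum())
    return EvalReport(confusion=confusion, accuracy=accuracy)


def _class_frame_index(true: np.ndarray, n_classes: int) -> list[np.ndarray]:
    return [np.flatnonzero(true == k) for k in range(n_classes)]


def _nearest_distance(frames: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Distance from each t to the nearest entry of sorted ``frames``."""
    pos = np.searchsorted(frames, t)
    left = np.where(pos > 0, np.abs(t - frames[np.maximum(pos - 1, 0)]), np.iinfo(int).max)
    right = np.where(
        pos < len(frames), np.abs(frames[np.minimum(pos, len(frames) - 1)] - t), np.iinfo(int).max
    )
    return np.minimum(left, right)


def _transition_frames(stream: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Map (from_class, to_class) -> sorted frames where the transition occurs."""
    idx = np.flatnonzero(np.diff(stream) != 0) + 1
    out: dict[tuple[int, int], list[int]] = {}
    for i in idx:
        out.setdefault((int(stream[i - 1]), int(stream[i])), []).append(int(i))
    return {k: np.array(v) for k, v in out.items()}


def misprediction_offsets(
    true: np.ndarray,
    pred: np.ndarray,
    rate_hz: float,
    n_classes: int = N_PHASES,
    per_event: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-misprediction time offsets in milliseconds.

    Default (per-frame): for each frame ``t`` with ``pred[t] != true[t]`` the
    offset is the distance to the nearest frame whose true class equals
    ``pred[t]``, times the frame duration.  Frames whose predicted class
    never occurs in the stream are returned separately (second array of
    frame indices), never silently dropped.

    ``per_event=True``: one offset per predicted class transition instead —
    the distance to the nearest true transition between the same class pair,
    so a stream whose boundaries are shifted by k frames yields the constant
    offset k.  Predicted transitions without a matching true transition pair
    are reported in the second array.
    """
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise DataError(f"length mismatch: true {true.shape} vs pred {pred.shape}")
    if per_event:
        true_tr = _transition_frames(true)
        offsets = []
        unmatched = []
        for pair, frames in _transition_frames(pred).items():
            if pair not in true_tr:
                unmatched.extend(frames.tolist())
                continue
            offsets.extend(
                (_nearest_distance(true_tr[pair], frames) * frame_ms(rate_hz)).tolist()
            )
        return np.sort(np.array(offsets)), np.array(sorted(unmatched), dtype=int)
    wrong = np.flatnonzero(pred != true)
    index = _class_frame_index(true, n_classes)
    offsets = []
    unmatched = []
    for k in range(n_classes):
        sel = wrong[pred[wrong] == k]
        if sel.size == 0:
            continue
        if index[k].size == 0:
            unmatched.extend(sel.tolist())
            continue
        offsets.extend((_nearest_distance(index[k], sel) * frame_ms(rate_hz)).tolist())
    return np.sort(np.array(offsets)), np.array(sorted(unmatched), dtype=int)


def tolerance_accuracy(
    true: np.ndarray,
    pred: np.ndarray,
    tol_frames: int,
    n_classes: int = N_PHASES,
) -> float:
    """Fraction of frames whose prediction matches the true class somewhere
    within ``tol_frames`` frames (symmetric); tol 0 is plain accuracy."""
    if tol_frames < 0:
        raise DataError("tol_frames must be >= 0")
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise DataError(f"length mismatch: true {true.shape} vs pred {pred.shape}")
    if true.size == 0:
        raise DataError("empty streams")
    index = _class_frame_index(true, n_classes)
    ok = np.zeros(true.shape, dtype=bool)
    t_all = np.arange(true.size)
    for k in range(n_classes):
        sel = t_all[pred == k]
        if sel.size == 0:
            continue
        if index[k].size == 0:
            continue
        ok[sel] = _nearest_distance(index[k], sel) <= tol_frames
    return float(np.mean(ok))


def reject_by_certainty(pred: PredictionSet, threshold: float) -> RejectionReport:
    """Assign windows with max-softmax certainty <= threshold to 'unknown'.

    Accuracy is recomputed on the retained set; when nothing is retained it
    is reported as None while all counts stay valid.
    """
    if not 0.0 <= threshold <= 1.0:
        raise DataError("threshold must be in [0, 1]")
    if pred.true is None:
        raise DataError("PredictionSet has no ground-truth labels")
    cert = pred.certainty
    correct = pred.pred == pred.true
    rejected = cert <= threshold
    n_total = int(cert.size)
    n_unknown = int(rejected.sum())
    n_cu = int((rejected & correct).sum())
    n_wu = int((rejected & ~correct).sum())
    retained = ~rejected
    acc = float(np.mean(correct[retained])) if retained.any() else None
    n_correct = int(correct.sum())
    n_wrong = n_total - n_correct
    return RejectionReport(
        threshold=threshold,
        accuracy_retained=acc,
        n_total=n_total,
        n_unknown=n_unknown,
        n_correct_to_unknown=n_cu,
        n_wrong_to_unknown=n_wu,
        frac_unknown=n_unknown / n_total,
        frac_correct_to_unknown=n_cu / n_correct if n_correct else 0.0,
        frac_wrong_to_unknown=n_wu / n_wrong if n_wrong else 0.0,
    )


def certainty_stats(values: np.ndarray) -> dict:
    """Box-plot style summary: quartiles, whiskers at 1.5*IQR, outliers."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo) & (values <= hi)]
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(values.size - inside.size),
    }


def loocv_summary(accuracies) -> dict:
    """Mean / sd (population) / median of per-subject LOOCV accuracies."""
    a = np.asarray(list(accuracies), dtype=float)
    if a.size == 0:
        raise DataError("no accuracies supplied")
    return {
        "mean": float(a.mean()),
        "sd": float(a.std(ddof=0)),
        "median": float(np.median(a)),
        "n": int(a.size),
    }


def loocv(
    dataset,
    model_cfg,
    train_cfg,
    *,
    window_spec=None,
    seq_len: int = 64,
    ic_stretch: int = 10,
    split_seed: int = 0,
) -> dict:
    """Leave-one-subject-out: one model per held-out subject.

    ``dataset`` is a list of (ImuRecording, PressureTrace, PhaseLabels)
    triples.  Returns per-subject accuracies plus summary statistics.
    """
    from gaitphase.pipeline import run_split  # local import avoids a cycle

    subject_ids = [imu.subject_id for imu, _, _ in dataset]
    if len(subject_ids) < 2:
        raise DataError("LOOCV needs at least 2 subjects")
    per_subject: dict[str, float] = {}
    for sid in subject_ids:
        try:
            result = run_split(
                dataset,
                unseen_subject=sid,
                model_cfg=model_cfg,
                train_cfg=train_cfg,
                window_spec=window_spec,
                seq_len=seq_len,
                ic_stretch=ic_stretch,
                split_seed=split_seed,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with subject context
            raise type(exc)(f"LOOCV failed for held-out subject {sid!r}: {exc}") from exc
        per_subject[sid] = result["unseen_accuracy"]
    return {"per_subject": per_subject, **loocv_summary(per_subject.values())}


def activation_heatmap(
    net,
    x: np.ndarray,
    target_shape: tuple[int, int] | None = None,
    channel_labels: list[str] | None = None,
) -> dict:
    """Mean absolute last-conv-layer activation over all windows and filters.

    The [h, w] grid is min-max normalized to [0, 1] (a constant grid maps to
    all zeros) and bilinearly upsampled to ``target_shape`` (default: the
    network's input resolution).  Returns the grid, the upsampled map, and
    optional per-column channel annotations.
    """
    if x.shape[0] == 0:
        raise DataError("no sequences supplied for the heatmap")
    feats = net.conv_features(x)  # [B*S, h, w, filters]
    grid = np.abs(feats).mean(axis=(0, 3)).astype(float)
    lo, hi = grid.min(), grid.max()
    norm = np.zeros_like(grid) if hi == lo else (grid - lo) / (hi - lo)
    if target_shape is None:
        target_shape = net.input_shape
    zoom = (target_shape[0] / norm.shape[0], target_shape[1] / norm.shape[1])
    upsampled = ndimage.zoom(norm, zoom, order=1)
    upsampled = np.clip(upsampled, 0.0, 1.0)
    out = {"grid": norm, "map": upsampled, "target_shape": tuple(target_shape)}
    if channel_labels is not None:
        # column c of the map covers input channels around c / width
        n_cols = len(channel_labels)
        spans = np.linspace(0, n_cols, norm.shape[1] + 1)
        out["column_channels"] = [
            channel_labels[int(spans[i]) : max(int(spans[i + 1]), int(spans[i]) + 1)]
            for i in range(norm.shape[1])
        ]
    return out


def save_heatmap(heatmap: dict, png_path, csv_path=None) -> None:
    """Persist an activation heatmap as PNG (and optionally the raw grid CSV)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(heatmap["map"], aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xlabel("input channel column")
    ax.set_ylabel("window frame")
    fig.colorbar(im, ax=ax, label="normalized mean |activation|")
    fig.tight_layout()
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    if csv_path is not None:
        np.savetxt(csv_path, heatmap["grid"], delimiter=",", fmt="%.6f")
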