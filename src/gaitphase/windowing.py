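"""Input representation: channel ordering, sequence chunking, sliding
windows, and leave-one-subject-out splits.

The classifier consumes overlapping windows of ``window_len`` frames by
``N*C`` channels.  Windows are grouped into fixed-length sequences (the unit
that is shuffled during training, preserving temporal order inside) and
every window carries the phase label of its designated frame (the last one
by default, supporting causal online prediction).

A sequence of ``seq_len`` windows at shift ``s`` is built from
``(seq_len - 1) * s + window_len`` consecutive raw frames.  With the
baseline shift of 1 this is ``seq_len + window_len - 1`` frames, so a
480-window sequence consumes 529 raw frames.  (The alternative convention —
a sequence is 480 *raw frames*, yielding 431 windows — is available via
``seq_unit="frames"``.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from gaitphase.errors import ConfigError, DataError
from gaitphase.types import CHANNELS, ImuRecording

__all__ = [
    "SequenceChunk",
    "SplitPlan",
    "WindowSet",
    "WindowSpec",
    "arrange_channels",
    "channel_names",
    "make_sequences",
    "make_windows",
    "select_sensors",
    "sequence_chunk_frames",
    "split_and_shuffle",
    "windows_to_tensors",
]


@dataclass
class WindowSpec:
    window_len: int = 50
    shift: int = 1
    channel_order: str = "by_device"
    label_frame: str = "last"

    def validate(self) -> None:
        if self.window_len < 1:
            raise ConfigError("window_len must be >= 1")
        if self.shift < 1:
            raise ConfigError("shift must be >= 1")
        if self.channel_order not in ("by_device", "by_measurement"):
            raise ConfigError(
                f"unknown channel_order {self.channel_order!r}; "
                "expected 'by_device' or 'by_measurement'"
            )
        if self.label_frame not in ("last", "center"):
            raise ConfigError(
                f"unknown label_frame {self.label_frame!r}; expected 'last' or 'center'"
            )


@dataclass
class SplitPlan:
    unseen_subject: str
    train_fraction: float = 0.66
    val_fraction_of_train: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if not 0 < self.val_fraction_of_train < 1:
            raise ConfigError("val_fraction_of_train must be in (0, 1)")


@dataclass
class SequenceChunk:
    """A contiguous run of raw frames from one subject."""

    samples: np.ndarray  # [chunk_frames x D]
    labels: np.ndarray  # [chunk_frames]
    subject_id: str
    sequence_id: int
    start_frame: int


@dataclass
class WindowSet:
    """Sliding windows plus per-window bookkeeping."""

    windows: np.ndarray  # [W x window_len x D]
    labels: np.ndarray  # [W]
    sequence_ids: np.ndarray  # [W]
    subject_ids: np.ndarray  # [W] (object/str)
    spec: WindowSpec = field(default_factory=WindowSpec)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def channel_order_permutation(n_sensors: int, n_channels: int, order: str) -> np.ndarray:
    """Column permutation mapping by-device storage to the requested order."""
    if order == "by_device":
        return np.arange(n_sensors * n_channels)
    if order == "by_measurement":
        return np.array(
            [n * n_channels + c for c in range(n_channels) for n in range(n_sensors)]
        )
    raise ConfigError(f"unknown channel_order {order!r}")


def arrange_channels(recording: ImuRecording, order: str = "by_device") -> np.ndarray:
    """Reorder columns: by_device puts channel c of sensor n at ``n*C + c``,
    by_measurement at ``c*N + n``.  Pure permutation; values unchanged."""
    perm = channel_order_permutation(
        recording.n_sensors, len(CHANNELS), order
    )
    return recording.samples[:, perm]


def channel_names(locations: tuple[str, ...], order: str = "by_device") -> list[str]:
    if order == "by_device":
        return [f"{loc}_{ch}" for loc in locations for ch in CHANNELS]
    if order == "by_measurement":
        return [f"{loc}_{ch}" for ch in CHANNELS for loc in locations]
    raise ConfigError(f"unknown channel_order {order!r}")


def select_sensors(recording: ImuRecording, locations: list[str]) -> ImuRecording:
    """Restrict a recording to a subset of sensor locations."""
    unknown = [l for l in locations if l not in recording.sensor_locations]
    if unknown:
        raise DataError(f"unknown sensor locations: {unknown}")
    n_ch = len(CHANNELS)
    cols = np.concatenate(
        [
            np.arange(n_ch) + recording.sensor_locations.index(loc) * n_ch
            for loc in locations
        ]
    )
    return ImuRecording(
        subject_id=recording.subject_id,
        samples=recording.samples[:, cols],
        rate_hz=recording.rate_hz,
        trigger_frame=recording.trigger_frame,
        sensor_locations=tuple(locations),
    )


def sequence_chunk_frames(seq_len: int, window_len: int, shift: int = 1) -> int:
    """Raw frames consumed by one sequence of ``seq_len`` windows."""
    return (seq_len - 1) * shift + window_len


def make_sequences(
    samples: np.ndarray,
    labels: np.ndarray,
    seq_len: int,
    spec: WindowSpec | None = None,
    *,
    subject_id: str = "subject",
    seq_unit: str = "windows",
    first_sequence_id: int = 0,
) -> list[SequenceChunk]:
    """Cut a subject's stream into consecutive, disjoint sequence chunks.

    ``seq_unit="windows"``: each chunk holds exactly ``seq_len`` windows.
    ``seq_unit="frames"``: each chunk holds ``seq_len`` raw frames.
    The trailing remainder is dropped.
    """
    spec = spec or WindowSpec()
    spec.validate()
    samples = np.asarray(samples)
    labels = np.asarray(labels)
    if samples.shape[0] != labels.shape[0]:
        raise DataError(
            f"samples ({samples.shape[0]}) and labels ({labels.shape[0]}) "
            "lengths differ"
        )
    if seq_unit == "windows":
        chunk = sequence_chunk_frames(seq_len, spec.window_len, spec.shift)
    elif seq_unit == "frames":
        chunk = seq_len
    else:
        raise ConfigError(f"unknown seq_unit {seq_unit!r}")
    if chunk < spec.window_len:
        raise ConfigError("sequence shorter than one window")

    out: list[SequenceChunk] = []
    T = samples.shape[0]
    for k, start in enumerate(range(0, T - chunk + 1, chunk)):
        out.append(
            SequenceChunk(
                samples=samples[start : start + chunk],
                labels=labels[start : start + chunk],
                subject_id=subject_id,
                sequence_id=first_sequence_id + k,
                start_frame=start,
            )
        )
    return out


def make_windows(
    sequence: SequenceChunk | np.ndarray,
    spec: WindowSpec,
    labels: np.ndarray | None = None,
    *,
    subject_id: str | None = None,
    sequence_id: int = 0,
) -> WindowSet:
    """Slide a window along one sequence; never spans sequence boundaries.

    Yields ``W = (L - window_len) // shift + 1`` windows; window ``w`` covers
    frames ``[w*shift, w*shift + window_len)`` and is labeled by the phase at
    its last (or center) frame.  Windows are verbatim slices: no filtering.
    """
    spec.validate()
    if isinstance(sequence, SequenceChunk):
        samples = sequence.samples
        labels = sequence.labels if labels is None else labels
        subject_id = sequence.subject_id if subject_id is None else subject_id
        sequence_id = sequence.sequence_id
    else:
        samples = np.asarray(sequence)
        if labels is None:
            raise DataError("labels required when sequence is a bare array")
        subject_id = subject_id or "subject"
    L = samples.shape[0]
    if L < spec.window_len:
        raise DataError(f"sequence length {L} < window_len {spec.window_len}")

    views = sliding_window_view(samples, spec.window_len, axis=0)  # [L-T+1, D, T]
    windows = views[:: spec.shift].transpose(0, 2, 1)  # [W, T, D]
    W = windows.shape[0]
    starts = np.arange(W) * spec.shift
    if spec.label_frame == "last":
        label_idx = starts + spec.window_len - 1
    else:
        label_idx = starts + spec.window_len // 2
    win_labels = np.asarray(labels)[label_idx]
    return WindowSet(
        windows=np.ascontiguousarray(windows),
        labels=win_labels,
        sequence_ids=np.full(W, sequence_id, dtype=int),
        subject_ids=np.array([subject_id] * W, dtype=object),
        spec=spec,
    )


def split_and_shuffle(
    sequences: list[SequenceChunk], plan: SplitPlan
) -> tuple[
    list[SequenceChunk], list[SequenceChunk], list[SequenceChunk], list[SequenceChunk]
]:
    """(train, val, test, unseen) partition at whole-sequence granularity.

    The unseen subject's sequences are isolated untouched; the rest are
    shuffled with the plan's seed and split train/test, with a fraction of
    train peeled off for validation.  Frames inside a sequence keep order.
    """
    plan.validate()
    subject_ids = {s.subject_id for s in sequences}
    if plan.unseen_subject not in subject_ids:
        raise DataError(
            f"unseen_subject {plan.unseen_subject!r} not among {sorted(subject_ids)}"
        )
    if len(subject_ids) < 2:
        raise DataError("need at least 2 subjects to hold one out")

    unseen = [s for s in sequences if s.subject_id == plan.unseen_subject]
    rest = [s for s in sequences if s.subject_id != plan.unseen_subject]
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(rest))
    shuffled = [rest[i] for i in order]

    n_train_total = int(round(plan.train_fraction * len(shuffled)))
    n_train_total = min(max(n_train_total, 1), len(shuffled) - 1)
    train_all = shuffled[:n_train_total]
    test = shuffled[n_train_total:]
    n_val = max(int(round(plan.val_fraction_of_train * len(train_all))), 1)
    n_val = min(n_val, len(train_all) - 1) if len(train_all) > 1 else 0
    val = train_all[:n_val]
    train = train_all[n_val:]
    return train, val, test, unseen


def windows_to_tensors(
    chunks: list[SequenceChunk], spec: WindowSpec, dtype=np.float32
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack equal-length sequence chunks into network-ready tensors.

    Returns ``(X [n_seq, S, window_len, D], y [n_seq, S], subject_ids [n_seq])``.
    """
    if not chunks:
        raise DataError("no sequence chunks supplied")
    xs, ys, sids = [], [], []
    for ch in chunks:
        ws = make_windows(ch, spec)
        xs.append(ws.windows.astype(dtype))
        ys.append(ws.labels.astype(np.int64))
        sids.append(ch.subject_id)
    lengths = {x.shape[0] for x in xs}
    if len(lengths) != 1:
        raise DataError(f"sequence chunks yield unequal window counts: {lengths}")
    return np.stack(xs), np.stack(ys), np.array(sids, dtype=object)
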