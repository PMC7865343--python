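"""End-to-end glue: raw streams -> labels -> windows -> model -> reports."""

from __future__ import annotations

import logging

import numpy as np

from gaitphase.errors import DataError
from gaitphase.labeling import align_streams, label_pressure_trace
from gaitphase.nn.network import (
    ModelConfig,
    TrainConfig,
    build_model,
    predict,
    train_model,
)
from gaitphase.types import CHANNELS, ImuRecording
from gaitphase.windowing import (
    SequenceChunk,
    SplitPlan,
    WindowSpec,
    arrange_channels,
    make_sequences,
    select_sensors,
    split_and_shuffle,
    windows_to_tensors,
)

logger = logging.getLogger(__name__)


def prepare_subject(
    imu,
    pressure,
    *,
    window_spec: WindowSpec,
    seq_len: int,
    ic_stretch: int = 10,
    sensor_subset: list[str] | None = None,
    truth_labels=None,
    first_sequence_id: int = 0,
) -> list[SequenceChunk]:
    """Align, label (from the pressure curve unless truth is supplied),
    arrange channels and cut one subject into sequence chunks."""
    imu_al, pressure_al, _ = align_streams(imu, pressure)
    if truth_labels is not None:
        labels = truth_labels.labels[: pressure_al.n_frames]
    else:
        labels = label_pressure_trace(pressure_al, ic_stretch=ic_stretch).labels
    if sensor_subset is not None:
        imu_al = select_sensors(imu_al, sensor_subset)
    samples = arrange_channels(imu_al, window_spec.channel_order)
    n = min(samples.shape[0], labels.shape[0])
    return make_sequences(
        samples[:n],
        labels[:n],
        seq_len,
        window_spec,
        subject_id=imu_al.subject_id,
        first_sequence_id=first_sequence_id,
    )


def run_split(
    dataset,
    unseen_subject: str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    *,
    window_spec: WindowSpec | None = None,
    seq_len: int = 64,
    ic_stretch: int = 10,
    split_seed: int = 0,
    sensor_subset: list[str] | None = None,
    use_truth_labels: bool = False,
) -> dict:
    """Train on all subjects but one, evaluate on test set and unseen subject.

    Returns a dict with the trained network, history, per-window
    PredictionSets and plain accuracies for the test and unseen sets.
    """
    window_spec = window_spec or WindowSpec()
    chunks: list[SequenceChunk] = []
    seq_id = 0
    for imu, pressure, truth in dataset:
        subject_chunks = prepare_subject(
            imu,
            pressure,
            window_spec=window_spec,
            seq_len=seq_len,
            ic_stretch=ic_stretch,
            sensor_subset=sensor_subset,
            truth_labels=truth if use_truth_labels else None,
            first_sequence_id=seq_id,
        )
        seq_id += len(subject_chunks)
        chunks.extend(subject_chunks)
    if not chunks:
        raise DataError("no sequence chunks produced; recordings too short?")

    plan = SplitPlan(unseen_subject=unseen_subject, seed=split_seed)
    train_chunks, val_chunks, test_chunks, unseen_chunks = split_and_shuffle(
        chunks, plan
    )
    Xtr, ytr, _ = windows_to_tensors(train_chunks, window_spec)
    Xval, yval, _ = windows_to_tensors(val_chunks, window_spec)
    Xte, yte, te_sids = windows_to_tensors(test_chunks, window_spec)
    Xun, yun, un_sids = windows_to_tensors(unseen_chunks, window_spec)

    cfg = model_cfg.resolved(seq_len)
    net = build_model(cfg, input_shape=Xtr.shape[2:])
    net, history = train_model(net, (Xtr, ytr), (Xval, yval), train_cfg)

    test_pred = predict(net, Xte, yte, te_sids)
    unseen_pred = predict(net, Xun, yun, un_sids)
    return {
        "net": net,
        "history": history,
        "window_spec": window_spec,
        "seq_len": seq_len,
        "test_pred": test_pred,
        "unseen_pred": unseen_pred,
        "test_accuracy": float(np.mean(test_pred.pred == test_pred.true)),
        "unseen_accuracy": float(np.mean(unseen_pred.pred == unseen_pred.true)),
        "n_train_seq": len(train_chunks),
        "n_val_seq": len(val_chunks),
        "n_test_seq": len(test_chunks),
        "n_unseen_seq": len(unseen_chunks),
    }
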