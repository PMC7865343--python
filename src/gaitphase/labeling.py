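"""Five-phase labels from a synchronized pressure trace.

The force curve of one step carries two maxima and an interior minimum; those
extrema, together with contact onset and toe-off, delimit the phases:

    IC: [contact, contact + ic_stretch)
    LR: [contact + ic_stretch, first peak)
    MS: [first peak, valley)
    TS: [valley, toe-off)
    SW: [toe-off, next contact)   (also before the first contact)

All indices are 0-based and intervals half-open.  Extrema are located on a
moving-average-smoothed copy of the trace (raw curves are not always smooth)
and then refined to the nearest raw-trace extremum, so indices always refer
to the raw trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from gaitphase.errors import AlignmentError, DataError
from gaitphase.types import (
    AlignmentInfo,
    GaitPhase,
    ImuRecording,
    PhaseLabels,
    PressureTrace,
    StepEvents,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentInfo",
    "DetectionResult",
    "GaitPhase",
    "PhaseLabels",
    "StepEvents",
    "align_streams",
    "detect_step_events",
    "events_to_labels",
    "label_pressure_trace",
]


def align_streams(
    imu: ImuRecording,
    pressure: PressureTrace,
    *,
    allow_resample: bool = False,
    max_sync_error_ms: float = 16.0,
) -> tuple[ImuRecording, PressureTrace, AlignmentInfo]:
    """Crop both streams so their trigger frames coincide at index 0.

    Lengths are truncated to the shorter stream.  If the rates differ the
    pressure trace is linearly interpolated onto the IMU rate, but only when
    ``allow_resample`` is set.
    """
    if imu.trigger_frame is None or pressure.trigger_frame is None:
        raise AlignmentError("both streams must carry a trigger_frame")

    force = pressure.force
    p_trigger = pressure.trigger_frame
    if pressure.rate_hz != imu.rate_hz:
        if not allow_resample:
            raise AlignmentError(
                f"rate mismatch ({pressure.rate_hz} Hz vs {imu.rate_hz} Hz) "
                "and resampling is disabled"
            )
        ratio = imu.rate_hz / pressure.rate_hz
        n_new = int(round((pressure.n_frames - 1) * ratio)) + 1
        t_new = np.arange(n_new) / imu.rate_hz
        t_old = np.arange(pressure.n_frames) / pressure.rate_hz
        force = np.interp(t_new, t_old, force)
        p_trigger = int(round(p_trigger * ratio))

    imu_cropped = imu.samples[imu.trigger_frame :]
    force_cropped = force[p_trigger:]
    n = min(imu_cropped.shape[0], force_cropped.shape[0])

    out_imu = ImuRecording(
        subject_id=imu.subject_id,
        samples=imu_cropped[:n],
        rate_hz=imu.rate_hz,
        trigger_frame=0,
        sensor_locations=imu.sensor_locations,
    )
    out_pressure = PressureTrace(
        force=force_cropped[:n], rate_hz=imu.rate_hz, trigger_frame=0
    )
    info = AlignmentInfo(
        imu_trigger_frame=imu.trigger_frame,
        pressure_trigger_frame=pressure.trigger_frame,
        max_sync_error_ms=max_sync_error_ms,
    )
    return out_imu, out_pressure, info


@dataclass
class DetectionResult:
    """Per-step events plus the stance intervals that could not be labeled."""

    steps: list[StepEvents]
    unlabelable: list[tuple[int, int]]


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # same-length smoothing; edges use the shrunken effective window
    smooth = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return smooth / norm


def _refine_extremum(
    force: np.ndarray, idx: int, lo: int, hi: int, window: int, kind: str
) -> int:
    """Snap a smoothed-trace extremum to the raw trace within +/- window."""
    a = max(lo, idx - window)
    b = min(hi, idx + window + 1)
    a = min(a, hi - 1)
    b = max(b, a + 1)
    seg = force[a:b]
    off = int(np.argmax(seg)) if kind == "max" else int(np.argmin(seg))
    return a + off


def detect_step_events(
    pressure: PressureTrace,
    contact_threshold: float | None = None,
    smooth_window: int = 5,
) -> DetectionResult:
    """Find per-step {contact, peak1, valley, peak2, toe-off} frames.

    A step is a contiguous supra-threshold (stance) interval.  Intervals
    shorter than ``2 * smooth_window`` frames are dropped as artifacts;
    intervals without two separable maxima are flagged unlabelable and
    logged, never silently mislabeled.  Stances still above threshold at the
    end of the trace are incomplete and ignored.
    """
    force = np.asarray(pressure.force, dtype=float)
    if np.any(force < 0):
        raise DataError("pressure trace contains negative force values")
    if contact_threshold is None:
        contact_threshold = 0.02 * force.max() if force.size and force.max() > 0 else 0.0

    above = force > contact_threshold
    # run-length encode the stance intervals
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above.size and above[0]:
        starts.insert(0, 0)
    if above.size and above[-1]:
        ends.append(len(force))  # incomplete final stance

    steps: list[StepEvents] = []
    unlabelable: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if e >= len(force) and above[-1]:
            logger.debug("dropping incomplete stance at trace end [%d, %d)", s, e)
            continue
        if e - s < 2 * smooth_window:
            logger.debug("dropping short stance artifact [%d, %d)", s, e)
            continue
        seg = _moving_average(force[s:e], smooth_window)
        # prominence filter separates the two true humps from noise wiggles
        peaks, props = find_peaks(seg, prominence=0.05 * float(seg.max()))
        if len(peaks) < 2:
            logger.warning(
                "stance [%d, %d) has %d separable maxima (need 2): unlabelable",
                s,
                e,
                len(peaks),
            )
            unlabelable.append((s, e))
            continue
        order = np.argsort(props["prominences"])[::-1]
        top2 = np.sort(peaks[order[:2]])
        p1 = _refine_extremum(force, s + int(top2[0]), s, e, smooth_window, "max")
        p2 = _refine_extremum(force, s + int(top2[1]), s, e, smooth_window, "max")
        if p1 == p2:
            unlabelable.append((s, e))
            continue
        v_smooth = s + int(top2[0]) + int(
            np.argmin(seg[int(top2[0]) : int(top2[1]) + 1])
        )
        valley = _refine_extremum(force, v_smooth, p1 + 1, p2, smooth_window, "min")
        steps.append(
            StepEvents(contact=s, peak1=p1, valley=valley, peak2=p2, toe_off=e)
        )
    return DetectionResult(steps=steps, unlabelable=unlabelable)


def events_to_labels(
    steps: list[StepEvents], n_frames: int, ic_stretch: int = 10
) -> PhaseLabels:
    """Fill a per-frame label vector from ordered step events.

    Frames before the first contact and after the last toe-off are swing.
    """
    if ic_stretch < 1:
        raise DataError("ic_stretch must be >= 1")
    labels = np.full(n_frames, int(GaitPhase.SW), dtype=np.int8)
    for k, ev in enumerate(steps):
        if not ev.ordered():
            raise DataError(f"step {k} events are not ordered: {ev}")
        if ic_stretch >= ev.peak1 - ev.contact:
            raise DataError(
                f"ic_stretch={ic_stretch} >= first peak - contact "
                f"({ev.peak1 - ev.contact}) for step {k}: IC would swallow LR"
            )
        labels[ev.contact : ev.contact + ic_stretch] = GaitPhase.IC
        labels[ev.contact + ic_stretch : ev.peak1] = GaitPhase.LR
        labels[ev.peak1 : ev.valley] = GaitPhase.MS
        labels[ev.valley : ev.toe_off] = GaitPhase.TS
        # toe_off .. next contact remains SW
    return PhaseLabels(labels=labels, event_frames=list(steps), ic_stretch=ic_stretch)


def label_pressure_trace(
    pressure: PressureTrace,
    ic_stretch: int = 10,
    contact_threshold: float | None = None,
    smooth_window: int = 5,
) -> PhaseLabels:
    """Detect events and fill labels in one call (the usual entry point)."""
    detection = detect_step_events(
        pressure, contact_threshold=contact_threshold, smooth_window=smooth_window
    )
    return events_to_labels(detection.steps, pressure.n_frames, ic_stretch=ic_stretch)
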