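"""Synthetic walking data: coupled IMU and pressure-plate streams.

Every downstream stage is tested against this generator, so it is built to
make its own ground truth exact: the force curve is a smooth two-bump stance
profile whose extrema are read off the constructed (noiseless) template, and
the per-frame labels are filled directly from those event frames.

Force model per stance interval (u in [0, 1) = fraction of stance): the sum
of two raised cosines centered at ``peak1_frac`` and ``peak2_frac`` with
amplitudes 1.0 and 0.95 and half-widths ``2*(valley_frac - peak1_frac)`` and
``2*(peak2_frac - valley_frac)``, which keeps force strictly positive on the
whole stance while leaving two separable maxima and one interior minimum.

IMU model per channel: ``a1*sin(2*pi*phi + psi1) + a2*sin(4*pi*phi + psi2)``
of the cycle phase ``phi``, parameters drawn once per sensor-channel from the
seeded RNG (shared across subjects), scaled by a per-subject log-normal gain
and corrupted with additive Gaussian noise.  The barometric channel is a
slowly drifting near-constant carrying no phase information.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from gaitphase.errors import ConfigError
from gaitphase.types import (
    CHANNELS,
    SENSOR_LOCATIONS,
    GaitPhase,
    ImuRecording,
    PhaseLabels,
    PressureTrace,
    StepEvents,
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic walking model."""

    n_subjects: int = 11
    duration_s: float = 60.0
    rate_hz: float = 120.0
    cycle_s_mean: float = 1.0
    cycle_s_sd: float = 0.05
    stance_fraction: float = 0.6
    peak1_frac: float = 0.30
    valley_frac: float = 0.50
    peak2_frac: float = 0.75
    noise_sd_imu: float = 0.05
    noise_sd_force: float = 0.0
    subject_gain_sd: float = 0.10
    ic_stretch: int = 10
    imu_trigger_frame: int = 0
    pressure_trigger_frame: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be > 0")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be > 0")
        if self.cycle_s_mean <= 0:
            raise ConfigError("cycle_s_mean must be > 0")
        if self.cycle_s_sd < 0:
            raise ConfigError("cycle_s_sd must be >= 0")
        if not 0 < self.stance_fraction < 1:
            raise ConfigError("stance_fraction must be in (0, 1)")
        if not 0 < self.peak1_frac < self.valley_frac < self.peak2_frac < 1:
            raise ConfigError(
                "peak1_frac, valley_frac, peak2_frac must satisfy "
                "0 < peak1_frac < valley_frac < peak2_frac < 1"
            )
        if self.noise_sd_imu < 0:
            raise ConfigError("noise_sd_imu must be >= 0")
        if self.noise_sd_force < 0:
            raise ConfigError("noise_sd_force must be >= 0")
        if self.subject_gain_sd < 0:
            raise ConfigError("subject_gain_sd must be >= 0")
        if self.ic_stretch < 1:
            raise ConfigError("ic_stretch must be >= 1")
        if self.imu_trigger_frame < 0:
            raise ConfigError("imu_trigger_frame must be >= 0")
        if self.pressure_trigger_frame < 0:
            raise ConfigError("pressure_trigger_frame must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


_N_CHANNELS = len(CHANNELS)
_BARO_INDEX = CHANNELS.index("p1")


def _raised_cosine(u: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """0.5*(1 + cos(pi*(u-center)/half_width)) inside the support, else 0."""
    x = (u - center) / half_width
    out = np.where(np.abs(x) < 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return out


def _stance_template(cfg: SyntheticConfig, stance_frames: int) -> np.ndarray:
    u = np.arange(stance_frames) / stance_frames
    # narrowest half-widths that keep force strictly positive on the whole
    # stance (supports must reach u=0, u=1 and overlap near the valley)
    w1 = max(cfg.peak1_frac, cfg.valley_frac - cfg.peak1_frac) + 0.05
    w2 = max(1.0 - cfg.peak2_frac, cfg.peak2_frac - cfg.valley_frac) + 0.05
    force = _raised_cosine(u, cfg.peak1_frac, w1) + 0.95 * _raised_cosine(
        u, cfg.peak2_frac, w2
    )
    return force


def _template_events(template: np.ndarray) -> tuple[int, int, int]:
    """(peak1, valley, peak2) frame offsets read off the noiseless template.

    Plateau maxima (two equal adjacent samples straddling the analytic peak)
    are resolved to their left edge, matching argmax semantics downstream.
    """
    peaks, props = find_peaks(template, plateau_size=1)
    maxima = props["left_edges"]
    if len(maxima) < 2:
        raise ConfigError(
            "stance_fraction/peak fractions yield a stance template without "
            "two separable force maxima; widen the peak spacing"
        )
    # the two tallest maxima, in temporal order
    top2 = sorted(sorted(maxima, key=lambda i: -template[i])[:2])
    p1, p2 = int(top2[0]), int(top2[1])
    valley = p1 + int(np.argmin(template[p1 : p2 + 1]))
    return p1, valley, p2


def _channel_params(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Waveform parameters per sensor-channel, shared across subjects."""
    rng = np.random.default_rng([cfg.seed, 0xC0FFEE])
    n = len(SENSOR_LOCATIONS) * _N_CHANNELS
    return {
        "a1": rng.uniform(0.6, 1.4, size=n),
        "a2": rng.uniform(0.2, 0.8, size=n),
        "psi1": rng.uniform(0.0, 2.0 * np.pi, size=n),
        "psi2": rng.uniform(0.0, 2.0 * np.pi, size=n),
        "baro_base": rng.uniform(0.9, 1.1, size=len(SENSOR_LOCATIONS)),
    }


def simulate_subject(
    cfg: SyntheticConfig, subject_index: int
) -> tuple[ImuRecording, PressureTrace, PhaseLabels]:
    """Generate one subject; identical (cfg, subject_index) => identical output.

    The returned :class:`PhaseLabels` is the generator's exact ground truth:
    events are read off the constructed noiseless force curve, and trailing
    frames that cannot hold a complete stance are emitted as swing.
    """
    cfg.validate()
    if not 0 <= subject_index < cfg.n_subjects:
        raise ConfigError(
            f"subject_index {subject_index} out of range for "
            f"n_subjects={cfg.n_subjects}"
        )

    T = cfg.n_frames
    params = _channel_params(cfg)
    rng = np.random.default_rng([cfg.seed, 1 + subject_index])

    cycle_s = rng.normal(cfg.cycle_s_mean, cfg.cycle_s_sd)
    cycle_s = max(cycle_s, 0.5 * cfg.cycle_s_mean)
    cycle_frames = max(int(round(cycle_s * cfg.rate_hz)), 4)
    stance_frames = max(int(round(cfg.stance_fraction * cycle_frames)), 3)

    template = _stance_template(cfg, stance_frames)
    tp1, tvalley, tp2 = _template_events(template)
    if cfg.ic_stretch >= tp1:
        raise ConfigError(
            f"ic_stretch={cfg.ic_stretch} would swallow the loading response "
            f"(first force peak at stance frame {tp1})"
        )

    # --- force trace and ground-truth labels on the post-trigger timeline ---
    force = np.zeros(T)
    labels = np.full(T, int(GaitPhase.SW), dtype=np.int8)
    events: list[StepEvents] = []
    start = 0
    while start + stance_frames < T:  # stance must complete within the trace
        force[start : start + stance_frames] = template
        ev = StepEvents(
            contact=start,
            peak1=start + tp1,
            valley=start + tvalley,
            peak2=start + tp2,
            toe_off=start + stance_frames,
        )
        events.append(ev)
        nxt = min(start + cycle_frames, T)
        labels[ev.contact : min(ev.contact + cfg.ic_stretch, nxt)] = GaitPhase.IC
        labels[ev.contact + cfg.ic_stretch : min(ev.peak1, nxt)] = GaitPhase.LR
        labels[ev.peak1 : min(ev.valley, nxt)] = GaitPhase.MS
        labels[ev.valley : min(ev.toe_off, nxt)] = GaitPhase.TS
        # toe_off .. next contact stays SW from the initial fill
        start += cycle_frames

    # --- IMU channels as phase-locked waveforms ---
    n_cols = len(SENSOR_LOCATIONS) * _N_CHANNELS
    t = np.arange(-cfg.imu_trigger_frame, T)  # pre-trigger frames included
    phi = (t % cycle_frames) / cycle_frames
    gains = np.exp(rng.normal(0.0, cfg.subject_gain_sd, size=n_cols))
    samples = np.empty((len(t), n_cols))
    for col in range(n_cols):
        samples[:, col] = gains[col] * (
            params["a1"][col] * np.sin(2 * np.pi * phi + params["psi1"][col])
            + params["a2"][col] * np.sin(4 * np.pi * phi + params["psi2"][col])
        )
    # overwrite barometric channels with a slowly drifting near-constant
    # (drift parametrized on the post-trigger timeline so trigger offsets
    # only prepend data instead of altering it)
    tt = t / max(T - 1, 1)
    for sensor in range(len(SENSOR_LOCATIONS)):
        col = sensor * _N_CHANNELS + _BARO_INDEX
        samples[:, col] = (
            params["baro_base"][sensor]
            + 0.02 * tt
            + 0.005 * np.sin(2 * np.pi * tt * 3.0)
        )
    if cfg.noise_sd_imu > 0:
        samples = samples + rng.normal(0.0, cfg.noise_sd_imu, size=samples.shape)

    if cfg.pressure_trigger_frame > 0:
        force = np.concatenate([np.zeros(cfg.pressure_trigger_frame), force])
    if cfg.noise_sd_force > 0:
        noisy = force + rng.normal(0.0, cfg.noise_sd_force, size=force.shape)
        force = np.where(force > 0, np.maximum(noisy, 1e-9), 0.0)

    imu = ImuRecording(
        subject_id=f"subject_{subject_index:02d}",
        samples=samples,
        rate_hz=cfg.rate_hz,
        trigger_frame=cfg.imu_trigger_frame,
    )
    pressure = PressureTrace(
        force=force,
        rate_hz=cfg.rate_hz,
        trigger_frame=cfg.pressure_trigger_frame,
    )
    truth = PhaseLabels(labels=labels, event_frames=events, ic_stretch=cfg.ic_stretch)
    return imu, pressure, truth


def simulate_dataset(
    cfg: SyntheticConfig,
) -> list[tuple[ImuRecording, PressureTrace, PhaseLabels]]:
    """All subjects; per-subject parameters drawn independently per subject."""
    cfg.validate()
    return [simulate_subject(cfg, i) for i in range(cfg.n_subjects)]


def write_subject(
    out_dir: str | Path,
    imu: ImuRecording,
    pressure: PressureTrace,
    truth: PhaseLabels | None = None,
    cfg: SyntheticConfig | None = None,
) -> Path:
    """Write one subject's streams as CSV plus a JSON sidecar.

    Layout: ``<out_dir>/<subject_id>/{imu.csv,force.csv,labels.csv,meta.json}``.
    """
    import pandas as pd

    subject_dir = Path(out_dir) / imu.subject_id
    subject_dir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(imu.samples, columns=imu.column_names).to_csv(
        subject_dir / "imu.csv", index=False, float_format="%.9g"
    )
    pd.DataFrame(
        {"frame": np.arange(pressure.n_frames), "force": pressure.force}
    ).to_csv(subject_dir / "force.csv", index=False, float_format="%.9g")
    if truth is not None:
        pd.DataFrame(
            {"frame": np.arange(truth.n_frames), "phase": truth.phase_codes()}
        ).to_csv(subject_dir / "labels.csv", index=False)

    meta: dict = {
        "subject_id": imu.subject_id,
        "rate_hz": imu.rate_hz,
        "imu_trigger_frame": imu.trigger_frame,
        "pressure_trigger_frame": pressure.trigger_frame,
        "sensor_locations": list(imu.sensor_locations),
    }
    if cfg is not None:
        meta["config"] = asdict(cfg)
    if truth is not None:
        meta["events"] = [asdict(ev) for ev in truth.event_frames]
        meta["ic_stretch"] = truth.ic_stretch
    (subject_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return subject_dir


def read_subject(
    subject_dir: str | Path,
) -> tuple[ImuRecording, PressureTrace, PhaseLabels | None]:
    """Read back what :func:`write_subject` wrote."""
    import pandas as pd

    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / "meta.json").read_text())
    imu_df = pd.read_csv(subject_dir / "imu.csv")
    force_path = subject_dir / "force.csv"
    if not force_path.exists():
        from gaitphase.errors import DataError

        raise DataError(f"missing force CSV: {force_path}")
    force_df = pd.read_csv(force_path)

    imu = ImuRecording(
        subject_id=meta["subject_id"],
        samples=imu_df.to_numpy(),
        rate_hz=meta["rate_hz"],
        trigger_frame=meta["imu_trigger_frame"],
        sensor_locations=tuple(meta["sensor_locations"]),
    )
    pressure = PressureTrace(
        force=force_df["force"].to_numpy(),
        rate_hz=meta["rate_hz"],
        trigger_frame=meta["pressure_trigger_frame"],
    )
    truth = None
    labels_path = subject_dir / "labels.csv"
    if labels_path.exists():
        codes = pd.read_csv(labels_path)["phase"]
        labels = np.array([GaitPhase[c] for c in codes], dtype=np.int8)
        events = [StepEvents(**ev) for ev in meta.get("events", [])]
        truth = PhaseLabels(
            labels=labels, event_frames=events, ic_stretch=meta.get("ic_stretch", 10)
        )
    return imu, pressure, truth
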