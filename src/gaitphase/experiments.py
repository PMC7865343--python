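"""Experiment drivers: greedy one-parameter sweeps and per-location
sensor-subset studies.

A sweep varies exactly one knob at a time (model field, sequence length,
channel order, or sensor subset) while everything else stays at the base
configuration, tabulating test and unseen-subject accuracy per candidate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from gaitphase.errors import ConfigError
from gaitphase.nn.network import ModelConfig, TrainConfig
from gaitphase.pipeline import run_split
from gaitphase.types import SENSOR_LOCATIONS
from gaitphase.windowing import WindowSpec

#: The five bilateral location pairs of the default sensor layout.
LOCATION_PAIRS: dict[str, list[str]] = {
    "foot": ["l_foot", "r_foot"],
    "tibia": ["l_tibia", "r_tibia"],
    "thigh": ["l_thigh", "r_thigh"],
    "hip": ["l_hip", "r_hip"],
    "arm": ["l_arm", "r_arm"],
}

_MODEL_FIELDS = {f.name for f in dataclasses.fields(ModelConfig)}
_SPECIAL_PARAMETERS = {"seq_len", "channel_order", "sensor_subset"}


@dataclass
class ExperimentConfig:
    """One greedy sweep: a parameter name and its candidate values."""

    parameter: str
    values: list
    sensor_subset: list[str] | None = None
    channel_order: str = "by_device"
    seeds: list[int] = field(default_factory=lambda: [0])

    def validate(self) -> None:
        if not self.values:
            raise ConfigError("candidate value list must be non-empty")
        if self.parameter not in _MODEL_FIELDS | _SPECIAL_PARAMETERS:
            raise ConfigError(
                f"unknown sweep parameter {self.parameter!r}; expected a "
                f"ModelConfig field or one of {sorted(_SPECIAL_PARAMETERS)}"
            )
        if self.sensor_subset is not None:
            unknown = [s for s in self.sensor_subset if s not in SENSOR_LOCATIONS]
            if unknown:
                raise ConfigError(f"unknown sensor locations: {unknown}")


def run_sweep(
    dataset,
    experiment: ExperimentConfig,
    unseen_subject: str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    *,
    window_spec: WindowSpec | None = None,
    seq_len: int = 64,
    ic_stretch: int = 10,
    split_seed: int = 0,
) -> list[dict]:
    """One trained model per candidate value; rows of
    ``{value, test_accuracy, unseen_accuracy}``."""
    experiment.validate()
    window_spec = window_spec or WindowSpec()
    rows: list[dict] = []
    for value in experiment.values:
        cfg = model_cfg
        wspec = window_spec
        slen = seq_len
        subset = experiment.sensor_subset
        if experiment.parameter == "seq_len":
            slen = int(value)
        elif experiment.parameter == "channel_order":
            wspec = dataclasses.replace(window_spec, channel_order=str(value))
        elif experiment.parameter == "sensor_subset":
            subset = LOCATION_PAIRS[value] if isinstance(value, str) else list(value)
        else:
            cfg = dataclasses.replace(model_cfg, **{experiment.parameter: value})
        try:
            result = run_split(
                dataset,
                unseen_subject=unseen_subject,
                model_cfg=cfg,
                train_cfg=train_cfg,
                window_spec=wspec,
                seq_len=slen,
                ic_stretch=ic_stretch,
                split_seed=split_seed,
                sensor_subset=subset,
            )
        except Exception as exc:  # noqa: BLE001 - keep candidate context
            raise type(exc)(
                f"sweep candidate {experiment.parameter}={value!r} failed: {exc}"
            ) from exc
        rows.append(
            {
                "value": value,
                "test_accuracy": result["test_accuracy"],
                "unseen_accuracy": result["unseen_accuracy"],
            }
        )
    return rows


def lstm_size_candidates(seq_len: int) -> list[int]:
    """The classic LSTM-size sweep: tiny, small, half, full, full + 20."""
    return [10, min(100, max(seq_len // 2, 10)), max(seq_len // 2, 1), seq_len, seq_len + 20]
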