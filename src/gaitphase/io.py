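"""Configuration files, manifests, checkpoints and report writers."""

from __future__ import annotations

import dataclasses
import json
import sys
from pathlib import Path

import numpy as np

from gaitphase import __version__
from gaitphase.errors import ConfigError, DataError
from gaitphase.nn.network import ConvLSTMNetwork, ModelConfig, TrainConfig
from gaitphase.synthetic import SyntheticConfig
from gaitphase.windowing import WindowSpec

_SECTION_TYPES = {
    "synthetic": SyntheticConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "windowing": WindowSpec,
}
_EXTRA_KEYS = {
    "windowing": {"seq_len"},
    "labeling": {"ic_stretch", "smooth_window", "contact_threshold"},
    "split": {"unseen_subject", "seed", "train_fraction", "val_fraction_of_train"},
    "sweep": {"parameter", "values", "sensor_subset", "channel_order", "seeds"},
}


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> dict:
    """Parse and validate the JSON run configuration.

    Unknown sections or keys are errors, not warnings.  Returns a dict with
    instantiated config objects under 'synthetic', 'model', 'train',
    'windowing' and plain dicts for 'labeling', 'split', 'sweep'.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"config {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must hold a JSON object at top level")
    _check_keys("<top>", raw, set(_SECTION_TYPES) | set(_EXTRA_KEYS))

    out: dict = {}
    for section, cls in _SECTION_TYPES.items():
        data = dict(raw.get(section, {}))
        allowed = {f.name for f in dataclasses.fields(cls)} | _EXTRA_KEYS.get(
            section, set()
        )
        _check_keys(section, data, allowed)
        extra = {k: data.pop(k) for k in list(data) if k in _EXTRA_KEYS.get(section, set())}
        for key in ("conv_kernels", "pool_kernels"):
            if key in data:
                data[key] = tuple(tuple(k) for k in data[key])
        for key in ("conv_filters", "dense_units"):
            if key in data:
                data[key] = tuple(data[key])
        try:
            obj = cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad config section {section!r}: {exc}") from exc
        if hasattr(obj, "validate"):
            obj.validate()
        out[section] = obj
        out.update({f"{section}.{k}": v for k, v in extra.items()})
    for section in ("labeling", "split", "sweep"):
        data = dict(raw.get(section, {}))
        _check_keys(section, data, _EXTRA_KEYS[section])
        out[section] = data
    return out


def write_manifest(out_dir: str | Path, config_echo: dict, seeds: dict) -> Path:
    """Everything needed to reproduce a run: config, seeds, versions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import scipy

    manifest = {
        "config": config_echo,
        "seeds": seeds,
        "versions": {
            "gaitphase": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_checkpoint(path: str | Path, net: ConvLSTMNetwork, extra: dict | None = None) -> None:
    """Weights as NPZ next to a JSON config echo (<path>.json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = net.get_weights()
    np.savez(path, **{f"w{i}": w for i, w in enumerate(weights)})
    meta = {
        "model_config": dataclasses.asdict(net.cfg),
        "input_shape": list(net.input_shape),
    }
    if extra:
        meta.update(extra)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=_json_default))


def load_checkpoint(path: str | Path) -> ConvLSTMNetwork:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    mc = dict(meta["model_config"])
    mc["conv_kernels"] = tuple(tuple(k) for k in mc["conv_kernels"])
    mc["pool_kernels"] = tuple(tuple(k) for k in mc["pool_kernels"])
    mc["conv_filters"] = tuple(mc["conv_filters"])
    mc["dense_units"] = tuple(mc["dense_units"])
    cfg = ModelConfig(**mc)
    net = ConvLSTMNetwork(cfg, tuple(meta["input_shape"]))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        weights = [data[f"w{i}"] for i in range(len(data.files))]
    net.set_weights(weights)
    return net


def write_history_csv(path: str | Path, history: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(history)[
        ["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
    ].to_csv(path, index=False)


def write_eval_report(out_dir: str | Path, name: str, report) -> None:
    """EvalReport as JSON plus the confusion matrix as CSV."""
    import pandas as pd

    from gaitphase.types import GaitPhase

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{name}_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=_json_default)
    )
    phases = [p.name for p in GaitPhase]
    pd.DataFrame(report.confusion, index=phases, columns=phases).to_csv(
        out_dir / f"{name}_confusion.csv"
    )
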