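"""File I/O: TIFF images, ROI/trajectory CSV, YAML configs, run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from punctaquant.kymo import AxonROI
from punctaquant.simulate import GolgiSimConfig, NoiseModel, TransportSimConfig


class ConfigError(ValueError):
    """Raised on schema violations in a config file."""


def write_image_tiff(path, image: np.ndarray) -> None:
    """Write an intensity image (or stack) as 16-bit TIFF, clipping at 65535."""
    arr = np.clip(np.round(np.asarray(image)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_roi_csv(path, roi: AxonROI) -> None:
    pd.DataFrame(roi.points, columns=["x", "y"]).to_csv(path, index=False)


def read_roi_csv(path, line_width: int = 1, soma_side: str = "start", pixel_size: float = 1.0) -> AxonROI:
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ConfigError(f"ROI CSV {path} missing column {col!r}")
    return AxonROI(
        points=df[["x", "y"]].to_numpy(float),
        line_width=line_width,
        soma_side=soma_side,
        pixel_size=pixel_size,
    )


def _config_from_mapping(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"config must be a mapping, got {type(data).__name__}")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - fields)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    if "seed" not in data:
        raise ConfigError("config files must set an explicit 'seed'")
    kwargs = dict(data)
    if "noise" in kwargs and isinstance(kwargs["noise"], dict):
        kwargs["noise"] = NoiseModel(**kwargs["noise"])
    for tup_key in ("cell_axes", "nucleus_axes"):
        if tup_key in kwargs and isinstance(kwargs[tup_key], list):
            kwargs[tup_key] = tuple(kwargs[tup_key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {cls.__name__}: {exc}") from exc


def load_transport_config(path) -> TransportSimConfig:
    with open(path) as fh:
        return _config_from_mapping(TransportSimConfig, yaml.safe_load(fh))


def load_golgi_config(path) -> GolgiSimConfig:
    with open(path) as fh:
        return _config_from_mapping(GolgiSimConfig, yaml.safe_load(fh))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(command: str, config: dict, seed: int | None, inputs: list) -> dict:
    """Provenance record written next to every pipeline output."""
    from punctaquant import __version__

    return {
        "tool": "punctaquant",
        "version": __version__,
        "command": command,
        "config": _jsonable(config),
        "seed": seed,
        "inputs": {str(p): sha256_file(p) for p in inputs if Path(p).exists()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_manifest(out_dir, manifest: dict) -> None:
    write_json(Path(out_dir) / "manifest.json", manifest)
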