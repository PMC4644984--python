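"""File formats, configuration and provenance.

Movies travel as multi-page TIFF (with a JSON sidecar for acquisition
metadata) or HDF5 (dataset ``"movie"`` with ``frame_interval_ms``,
``pixel_pitch_mm`` and ``channel`` attributes). Ground truth and fits are
JSON; micrographs are per-channel TIFF; tables are CSV. Every artefact a
run writes is tied to a config hash and a seed through the provenance
record.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import tifffile
import yaml

from opticard import __version__
from opticard.stack import MovieStack

__all__ = [
    "save_movie_h5", "load_movie_h5",
    "save_movie_tiff", "load_movie_tiff",
    "save_image_tiff", "load_image_tiff",
    "save_json", "load_json",
    "load_config", "config_hash",
    "RunManifest", "write_provenance",
]


def save_movie_h5(path: str | Path, m: MovieStack) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("movie", data=m.data.astype(np.float32))
        ds.attrs["frame_interval_ms"] = m.frame_interval
        ds.attrs["pixel_pitch_mm"] = m.pixel_pitch
        ds.attrs["channel"] = m.channel


def load_movie_h5(path: str | Path) -> MovieStack:
    with h5py.File(path, "r") as fh:
        ds = fh["movie"]
        return MovieStack(
            data=ds[...],
            frame_interval=float(ds.attrs["frame_interval_ms"]),
            pixel_pitch=float(ds.attrs["pixel_pitch_mm"]),
            channel=str(ds.attrs["channel"]),
        )


def save_movie_tiff(path: str | Path, m: MovieStack) -> None:
    """Multi-page float32 TIFF plus a ``.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, m.data.astype(np.float32))
    sidecar = {
        "frame_interval_ms": m.frame_interval,
        "pixel_pitch_mm": m.pixel_pitch,
        "channel": m.channel,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_movie_tiff(path: str | Path) -> MovieStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return MovieStack(
        data=tifffile.imread(path),
        frame_interval=float(meta["frame_interval_ms"]),
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        channel=str(meta["channel"]),
    )


def save_image_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def load_image_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if math.isfinite(v) else repr(v)
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    return obj


def save_json(path: str | Path, obj: Any) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def load_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Inputs and condition labels of one analysis run.

    ``samples`` maps sample id -> {"path", "role", "group", "atr_um",
    "opsin"}; every sample must carry exactly one group and one dose.
    """

    samples: dict[str, dict[str, Any]]
    seed: int = 0
    config: dict = field(default_factory=dict)

    def validate(self, check_paths: bool = True) -> None:
        for sid, rec in self.samples.items():
            for key in ("path", "role", "group", "atr_um"):
                if key not in rec:
                    raise ValueError(f"sample {sid!r} missing field {key!r}")
            if check_paths and not Path(rec["path"]).exists():
                raise FileNotFoundError(f"sample {sid!r}: missing input {rec['path']}")

    def to_json(self, path: str | Path) -> None:
        save_json(path, {"samples": self.samples, "seed": self.seed,
                         "config": self.config,
                         "config_hash": config_hash(self.config)})

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        raw = load_json(path)
        return cls(samples=raw["samples"], seed=int(raw["seed"]),
                   config=raw.get("config", {}))


def write_provenance(path: str | Path, seed: int, config: dict,
                     stages: list[str]) -> None:
    """Machine-readable record of what produced a run directory."""
    import datetime

    save_json(path, {
        "package": "opticard",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "stages": stages,
        "written_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    })
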