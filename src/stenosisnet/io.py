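"""Configuration loading, NIfTI volume I/O and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .network import NetworkConfig
from .phantom import PhantomConfig
from .training import TrainConfig

try:  # package version for manifests
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("stenosisnet")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for every pipeline stage."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return {
            "phantom": self.phantom.to_dict(),
            "network": self.network.to_dict(),
            "training": self.training.to_dict(),
        }


_SECTIONS = {"phantom": PhantomConfig, "network": NetworkConfig, "training": TrainConfig}
_LIST_FIELDS = {"stenosis_fraction_range", "volume_shape", "class_weights"}


def _build_section(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _LIST_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)  # dataclass __post_init__ enforces the invariants


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing sections/keys get defaults.

    Unknown sections or keys are rejected with a message naming them; every
    section's invariants (including the 21 -> 11 -> 6 network shape contract)
    are enforced on construction.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping of sections")
    if overrides:
        for sec, vals in overrides.items():
            data.setdefault(sec, {}).update(vals)
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    sections = {name: _build_section(cls, data.get(name, {}) or {})
                for name, cls in _SECTIONS.items()}
    return RunConfig(**sections)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_volume(path: str | Path, volume: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a 3D volume as NIfTI-1 (float64, identity affine by default)."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a 3D NIfTI volume; intensities as stored, 0-based voxel indexing.

    Returns (array, metadata); 4D or otherwise non-3D images are rejected.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    meta = {
        "affine": np.asarray(img.affine),
        "shape": tuple(img.shape),
        "index_convention": "0-based voxel indices, axis order (x, y, z) as stored",
    }
    return data, meta


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    stage: str,
    seed: int | None,
    config: dict,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> dict:
    """Write a JSON run manifest: config echo, seeds, version, file digests."""
    manifest = {
        "stage": stage,
        "version": _VERSION,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).is_file()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
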