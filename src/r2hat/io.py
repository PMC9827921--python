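"""NIfTI map container, configuration files and provenance records.

Maps are NIfTI-1, RAS+ world convention, float32 on disk; B0 is assumed
along the world z-axis.  R2* maps carry units of 1/s, slope maps 1/s per
degree, angle maps degrees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .params import EchoTimes, HCMParams, NoiseModel, SequenceParams

__all__ = [
    "QuantMap",
    "read_nifti",
    "write_nifti",
    "read_stack",
    "load_config",
    "config_hash",
    "sequence_from_config",
    "noise_from_config",
    "hcm_from_config",
    "echo_times_from_config",
    "provenance_record",
]


@dataclass
class QuantMap:
    """A 3-D (or 4-D) physical map with geometry and provenance."""

    data: np.ndarray
    affine: np.ndarray
    units: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self):
        return self.data.shape

    def same_geometry(self, other: "QuantMap", atol: float = 1e-5) -> bool:
        return (
            self.data.shape[:3] == other.data.shape[:3]
            and np.allclose(self.affine, other.affine, atol=atol)
        )


def read_nifti(path, units: str = "") -> QuantMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    side = Path(str(path) + ".json")
    prov = {}
    if side.exists():
        meta = json.loads(side.read_text())
        prov = meta.get("provenance", {})
        units = units or meta.get("units", "")
    return QuantMap(data, img.affine, units=units, provenance=prov)


def write_nifti(qmap: QuantMap, path) -> None:
    """Write float32 NIfTI-1 plus a JSON sidecar with units and provenance."""
    img = nib.Nifti1Image(qmap.data.astype(np.float32), qmap.affine)
    nib.save(img, str(path))
    meta = {"units": qmap.units, "provenance": qmap.provenance}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_stack(paths, units: str = "") -> list[QuantMap]:
    """Read several maps that must share geometry.

    Raises with both affines printed on the first mismatch.
    """
    maps = [read_nifti(p, units) for p in paths]
    ref = maps[0]
    for p, m in zip(paths[1:], maps[1:]):
        if not ref.same_geometry(m):
            raise ValueError(
                f"geometry mismatch between {paths[0]} and {p}:\n"
                f"{ref.affine}\nvs\n{m.affine}"
            )
    return maps


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    """Flat key-value configuration (YAML)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of flat keys")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _from_keys(cls, cfg: dict, prefix: str):
    names = {f.name for f in dc_fields(cls)}
    kwargs = {}
    for key, value in cfg.items():
        if key.startswith(prefix):
            name = key[len(prefix):]
            if name in names:
                kwargs[name] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


def sequence_from_config(cfg: dict) -> SequenceParams:
    return _from_keys(SequenceParams, cfg, "seq_")


def noise_from_config(cfg: dict) -> NoiseModel:
    return _from_keys(NoiseModel, cfg, "noise_")


def hcm_from_config(cfg: dict) -> HCMParams:
    return _from_keys(HCMParams, cfg, "hcm_")


def echo_times_from_config(cfg: dict) -> EchoTimes:
    if "te_list" in cfg:
        return EchoTimes(tuple(cfg["te_list"]))
    return EchoTimes()


def provenance_record(cfg: dict | None = None, seed: int | None = None) -> dict:
    import numpy
    from . import __version__

    return {
        "package": f"r2hat {__version__}",
        "numpy": numpy.__version__,
        "config_hash": config_hash(cfg or {}),
        "seed": seed,
    }
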