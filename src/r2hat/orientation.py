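"""Fiber-orientation analysis: angle to B0, vector reorientation, binning
and the sin^4(theta) hollow-cylinder fit.

B0 is taken along the world z-axis.  Fiber directions are axes, not
vectors, so the angle uses |v_z| and lies in [0, 90] degrees (antipodal
symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import polar

__all__ = [
    "fiber_angle",
    "reorient_vectors",
    "bin_by_angle",
    "fit_sin4",
    "Sin4Fit",
    "OrientationConfig",
    "select_wm_voxels",
]


@dataclass(frozen=True)
class OrientationConfig:
    """Voxel-selection and binning settings for the orientation analysis."""

    wm_prob_threshold: float = 0.9
    fa_threshold: float = 0.6
    bin_size: int = 200

    def __post_init__(self) -> None:
        for name, v in (("wm_prob_threshold", self.wm_prob_threshold),
                        ("fa_threshold", self.fa_threshold)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.bin_size < 2:
            raise ValueError("bin_size must be >= 2")


def fiber_angle(vectors) -> np.ndarray:
    """Angle (degrees) between fiber direction(s) and B0 (world z).

    ``vectors``: (..., 3).  theta = arccos(|v_z| / |v|); zero vectors
    (no fiber) yield NaN.
    """
    v = np.asarray(vectors, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("vectors must have a trailing axis of length 3")
    norm = np.linalg.norm(v, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_t = np.clip(np.abs(v[..., 2]) / norm, 0.0, 1.0)
        theta = np.degrees(np.arccos(cos_t))
    return np.where(norm > 0, theta, np.nan)


def reorient_vectors(vectors, transform) -> np.ndarray:
    """Rotate fiber directions into a new head position.

    ``transform`` is a 3x3 linear map or 4x4 affine between acquisition
    spaces; only its rotation factor (polar decomposition) is applied so
    that shears and scales cannot distort directions.  Vectors are
    renormalised; zero vectors stay zero.
    """
    v = np.asarray(vectors, dtype=float)
    t = np.asarray(transform, dtype=float)
    if t.shape == (4, 4):
        t = t[:3, :3]
    if t.shape != (3, 3):
        raise ValueError("transform must be 3x3 or a 4x4 affine")
    if abs(np.linalg.det(t)) < np.finfo(float).eps:
        raise ValueError("transform is singular")
    rot, _ = polar(t)
    out = v @ rot.T
    norm = np.linalg.norm(out, axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(norm > 0, out / norm, 0.0)
    return unit


def select_wm_voxels(wm_prob, fa, config: OrientationConfig = OrientationConfig()):
    """Boolean mask of white-matter voxels for the orientation analysis."""
    wm = np.asarray(wm_prob, dtype=float)
    f = np.asarray(fa, dtype=float)
    if wm.shape != f.shape:
        raise ValueError("WM probability and FA maps must share shape")
    return (wm > config.wm_prob_threshold) & (f > config.fa_threshold)


def bin_by_angle(theta_values, r2_values, bin_size: int = 200):
    """Equal-count angle bins: voxels sorted by theta, grouped in runs of
    exactly ``bin_size`` (the trailing partial bin is dropped), per-bin
    means returned as ``(theta_mean, r2_mean)`` arrays.

    Ties in theta are broken by the voxel's linear index for determinism.
    """
    theta = np.asarray(theta_values, dtype=float).reshape(-1)
    r2 = np.asarray(r2_values, dtype=float).reshape(-1)
    if theta.shape != r2.shape:
        raise ValueError("theta and R2* arrays must have the same length")
    keep = np.isfinite(theta) & np.isfinite(r2)
    theta, r2 = theta[keep], r2[keep]
    if theta.size < bin_size:
        raise ValueError(
            f"{theta.size} voxels is fewer than one bin of {bin_size}"
        )
    order = np.argsort(theta, kind="stable")
    n_bins = theta.size // bin_size
    idx = order[: n_bins * bin_size].reshape(n_bins, bin_size)
    return theta[idx].mean(axis=1), r2[idx].mean(axis=1)


@dataclass(frozen=True)
class Sin4Fit:
    """R2*(theta) = r2_iso + r2_aniso * sin^4(theta)."""

    r2_iso: float
    r2_aniso: float

    @property
    def ratio(self) -> float:
        if self.r2_iso == 0:
            raise ValueError("ratio undefined for zero isotropic component")
        return self.r2_aniso / self.r2_iso


def fit_sin4(theta_deg, r2_values) -> Sin4Fit:
    """Least-squares fit of the hollow-cylinder orientation dependence.

    Linear regression of R2* on sin^4(theta); returns the isotropic
    intercept and anisotropic amplitude (both 1/s).
    """
    theta = np.asarray(theta_deg, dtype=float).reshape(-1)
    y = np.asarray(r2_values, dtype=float).reshape(-1)
    if theta.size < 2:
        raise ValueError("need at least 2 bins")
    x = np.sin(np.deg2rad(theta)) ** 4
    if np.ptp(x) < np.finfo(float).eps:
        raise ValueError("all angles equal; sin^4 regressor is degenerate")
    design = np.stack([np.ones_like(x), x], axis=1)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return Sin4Fit(r2_iso=float(beta[0]), r2_aniso=float(beta[1]))
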