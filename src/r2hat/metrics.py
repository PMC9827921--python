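"""Quantitative error, sensitivity and reproducibility summaries.

Conventions fixed package-wide: standard deviations use the sample (n-1)
normalisation; percentages are returned on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "rmse_over_conditions",
    "rms_percent",
    "sensitivity_max_variation",
    "cov_fa",
    "cov_alpha",
    "session_bias_ci",
    "bland_altman",
    "SessionComparison",
    "BlandAltman",
]


def rmse_over_conditions(errors) -> float:
    """Root-mean-square of the model errors across tissue conditions (1/s)."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("no conditions")
    return float(np.sqrt(np.mean(e * e)))


def rms_percent(errors, r2star_simulated) -> float:
    """RMS percentage error across conditions.

    Each condition's error is expressed as a percentage of that condition's
    simulated R2* before squaring; the mean over conditions is taken inside
    the square root.
    """
    e = np.asarray(errors, dtype=float)
    r = np.asarray(r2star_simulated, dtype=float)
    if e.shape != r.shape:
        raise ValueError("errors and reference values must have the same shape")
    if np.any(r == 0):
        raise ValueError("reference R2* contains zeros; percentage undefined")
    q = 100.0 * e / r
    return float(np.sqrt(np.mean(q * q)))


def sensitivity_max_variation(values: np.ndarray, axis: int) -> float:
    """Maximum variation over the mean, in percent, along one grid axis.

    ``values`` is a complete rectangular grid of a model component; for
    each level of the other axes the spread along ``axis`` is summarised as
    100 * (max - min) / mean, and the maximum over levels is returned.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[axis] < 2:
        raise ValueError("axis must have at least 2 levels")
    if not np.all(np.isfinite(v)):
        raise ValueError("grid contains non-finite values")
    spread = v.max(axis=axis) - v.min(axis=axis)
    mean = v.mean(axis=axis)
    if np.any(mean == 0):
        raise ValueError("zero mean along axis; sensitivity undefined")
    return float(np.max(100.0 * spread / mean))


def cov_fa(maps, mask=None) -> float:
    """Median across voxels of the coefficient of variation across maps.

    ``maps``: stack with the map axis first, shape (n_maps, ...); per voxel
    100 * std(maps) / mean(maps) (sample std) is computed and the median is
    taken over in-mask voxels with nonzero mean (excluded voxels are
    dropped).
    """
    stack = np.asarray(maps, dtype=float)
    if stack.ndim < 2 or stack.shape[0] < 2:
        raise ValueError("need at least 2 maps")
    flat = stack.reshape(stack.shape[0], -1)
    if mask is not None:
        m = np.asarray(mask, dtype=bool).reshape(-1)
        if not m.any():
            raise ValueError("mask selects no voxels")
        flat = flat[:, m]
    valid = np.all(np.isfinite(flat), axis=0)
    flat = flat[:, valid]
    mean = flat.mean(axis=0)
    nz = mean != 0
    cov = 100.0 * flat[:, nz].std(axis=0, ddof=1) / mean[nz]
    if cov.size == 0:
        raise ValueError("no voxels with nonzero mean")
    return float(np.median(cov))


def cov_alpha(values) -> float:
    """Coefficient of variation (percent) of scalar per-alpha estimates."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean; COV undefined")
    return float(100.0 * v.std(ddof=1) / mean)


@dataclass(frozen=True)
class SessionComparison:
    bias: float  # 1/s
    ci95: float  # 1/s


def session_bias_ci(diff_stack) -> SessionComparison:
    """Inter-session bias and 95% interval from per-voxel differences.

    ``diff_stack``: (n_alpha_pairs, n_voxels) voxel-wise differences
    between sessions, one row per flip-angle pair.  The per-voxel median
    across pairs is summarised by its mean (bias) and 1.96 x its standard
    deviation across voxels (CI).
    """
    d = np.asarray(diff_stack, dtype=float)
    if d.ndim != 2:
        raise ValueError("diff_stack must be (n_pairs, n_voxels)")
    med = np.median(d, axis=0)
    med = med[np.isfinite(med)]
    if med.size < 2:
        raise ValueError("too few voxels")
    return SessionComparison(
        bias=float(np.mean(med)), ci95=float(1.96 * np.std(med, ddof=1))
    )


@dataclass(frozen=True)
class BlandAltman:
    mean: np.ndarray
    difference: np.ndarray
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(map_a, map_b, mask=None) -> BlandAltman:
    """Paired (mean, difference) samples with bias and limits of agreement."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a, b = a.reshape(-1), b.reshape(-1)
    if mask is not None:
        m = np.asarray(mask, dtype=bool).reshape(-1)
        a, b = a[m], b[m]
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    diff = b - a
    mean = 0.5 * (a + b)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return BlandAltman(mean, diff, bias, bias - 1.96 * sd, bias + 1.96 * sd)
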