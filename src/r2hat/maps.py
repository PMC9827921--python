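"""Voxel-wise map fitting pipelines.

Thin vectorised wrappers that run the estimators over masked voxels of 4-D
multi-echo volumes and return 3-D parameter maps (NaN outside the mask or
where a fit fails, so failed voxels drop out of downstream statistics).
"""

from __future__ import annotations

import numpy as np

from .fits import AlphaLinearModel, EstaticsR2Star, LogLinearR2Star
from .params import EchoTimes

__all__ = [
    "fit_r2star_map",
    "fit_estatics_map",
    "fit_linear_model_maps",
    "per_alpha_r2star_maps",
    "pair_maps",
]


def _masked(vol4d: np.ndarray, mask: np.ndarray | None):
    vol4d = np.asarray(vol4d, dtype=float)
    if vol4d.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, echo) volume")
    if mask is None:
        mask = np.ones(vol4d.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol4d.shape[:3]:
        raise ValueError("mask shape does not match volume")
    return vol4d, mask


def fit_r2star_map(vol4d, te: EchoTimes, mask=None) -> np.ndarray:
    """Log-linear R2* (1/s) per voxel of one multi-echo volume."""
    vol4d, mask = _masked(vol4d, mask)
    out = np.full(vol4d.shape[:3], np.nan)
    out[mask] = LogLinearR2Star().fit(te, vol4d[mask]).r2star_
    return out


def fit_estatics_map(vols, te_list, mask=None) -> np.ndarray:
    """Shared-decay R2* (1/s) from several flip-angle volumes."""
    vols = [np.asarray(v, dtype=float) for v in vols]
    ref_shape = vols[0].shape[:3]
    for v in vols:
        if v.shape[:3] != ref_shape:
            raise ValueError("volumes do not share geometry")
    if mask is None:
        mask = np.ones(ref_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    est = EstaticsR2Star().fit(list(te_list), [v[mask] for v in vols])
    out = np.full(ref_shape, np.nan)
    out[mask] = est.r2star_
    return out


def per_alpha_r2star_maps(vfa: dict, te: EchoTimes, mask=None) -> dict:
    """One R2* map per nominal flip angle from a VFA volume dictionary."""
    return {a: fit_r2star_map(vol, te, mask) for a, vol in vfa.items()}


def fit_linear_model_maps(
    r2_maps: dict, b1: np.ndarray | None = None, mask=None
):
    """Voxel-wise linear flip-angle model from per-alpha R2* maps.

    ``r2_maps``: {alpha_deg: 3-D map}; ``b1``: per-voxel efficiency map
    (default 1 everywhere).  Returns ``(r2star_hat, slope, residuals)``
    with residuals stacked over the alpha axis last.
    """
    alphas = np.array(sorted(r2_maps), dtype=float)
    if alphas.size < 2:
        raise ValueError("need at least 2 flip angles")
    stack = np.stack([np.asarray(r2_maps[a], dtype=float) for a in alphas], axis=-1)
    shape = stack.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    mask = mask & np.all(np.isfinite(stack), axis=-1)
    if b1 is None:
        b1_vals = np.ones(int(mask.sum()))
    else:
        b1 = np.asarray(b1, dtype=float)
        if b1.shape != shape:
            raise ValueError("B1 map shape does not match R2* maps")
        b1_vals = b1[mask]
    est = AlphaLinearModel().fit(alphas, stack[mask], b1_vals)
    r2hat = np.full(shape, np.nan)
    slope = np.full(shape, np.nan)
    resid = np.full(shape + (alphas.size,), np.nan)
    r2hat[mask] = est.r2star_hat_
    slope[mask] = est.dr2star_dalpha_
    resid[mask] = est.residuals_
    return r2hat, slope, resid


def pair_maps(
    vfa: dict,
    pairs,
    te: EchoTimes,
    b1: np.ndarray | None = None,
    mask=None,
):
    """ESTATICS and linear-model intercept maps for flip-angle pairs.

    For each (alpha_low, alpha_high) pair, returns the pooled shared-decay
    R2* map and the flip-angle-independent R2*^ map derived from the two
    per-alpha fits.  Output: {pair: {"estatics": map, "r2star_hat": map}}.
    """
    per_alpha = per_alpha_r2star_maps(vfa, te, mask)
    out = {}
    for pair in pairs:
        a1, a2 = (float(pair[0]), float(pair[1]))
        est = fit_estatics_map([vfa[a1], vfa[a2]], [te, te], mask)
        r2hat, _, _ = fit_linear_model_maps(
            {a1: per_alpha[a1], a2: per_alpha[a2]}, b1, mask
        )
        out[(a1, a2)] = {"estatics": est, "r2star_hat": r2hat}
    return out
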