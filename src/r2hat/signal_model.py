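"""Net multi-echo signal assembly, compartment frequency offsets and noise.

The net magnitude signal at echo time t is

    S_net(t) = | S_MW exp(-t (R2_MW + i dW_MW)) + S_IE exp(-t (R2_IE + i dW_IE)) |

with the pool decay rates approximated by 1/T2 of each pool and per-pool
bulk frequency offsets dW taken from the hollow-cylinder fiber model when
orientation effects are simulated (zero otherwise).
"""

from __future__ import annotations

import numpy as np

from .epgx import PoolSignal
from .params import EchoTimes, HCMParams, NoiseModel, PoolParams

__all__ = [
    "EchoTrain",
    "synthesize_echo_train",
    "hcm_offsets",
    "add_complex_noise",
    "batch_echo_trains",
]


class EchoTrain:
    """Signal samples over a TE vector.

    ``values`` has the echo axis last; ``is_magnitude`` marks magnitude
    (non-negative) trains.
    """

    def __init__(self, values, te: EchoTimes, is_magnitude: bool = True):
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != te.ms.size:
            raise ValueError(
                f"train has {values.shape[-1]} samples but {te.ms.size} echo times"
            )
        if is_magnitude and np.any(values < 0):
            raise ValueError("magnitude trains must be non-negative")
        self.values = values
        self.te = te
        self.is_magnitude = bool(is_magnitude)

    def __len__(self) -> int:
        return self.te.ms.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"EchoTrain(n_echo={len(self)}, shape={self.values.shape})"


def hcm_offsets(theta: float, hcm: HCMParams) -> tuple[float, float]:
    """Bulk frequency offsets (rad/s) of the MW and IE pools at fiber
    angle ``theta`` (degrees) under the hollow-cylinder fiber model.

    The myelin-water offset combines the isotropic and anisotropic
    susceptibility of the sheath plus a chemical-shift term; the merged
    IE-pool offset is the intra-axonal term weighted by the fraction of IE
    water inside the axon (the extra-axonal mean offset vanishes).  The
    angular dependence enters only through sin^2(theta).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0.0) or np.any(theta > 90.0):
        raise ValueError("theta must lie in [0, 90] degrees")
    s2 = np.sin(np.deg2rad(theta)) ** 2
    g = hcm.g_ratio
    ln_inv_g = np.log(1.0 / g)
    # myelin compartment (hollow cylinder interior of the sheath)
    dnu_mw = (
        hcm.chi_iso / 2.0 * (2.0 / 3.0 - s2)
        + hcm.chi_aniso
        / 2.0
        * (s2 * (-5.0 / 12.0 + 0.75 * (g * g / (1.0 - g * g)) * ln_inv_g) + 1.0 / 3.0)
        + hcm.e_term
    )
    # intra-axonal water, diluted into the merged IE pool
    dnu_ie = hcm.intra_axonal_weight * 0.75 * hcm.chi_aniso * s2 * ln_inv_g
    to_rad_s = hcm.gamma_b0 * 1e-6  # ppm -> rad/s
    if theta.ndim == 0:
        return float(dnu_mw * to_rad_s), float(dnu_ie * to_rad_s)
    return dnu_mw * to_rad_s, dnu_ie * to_rad_s


def synthesize_echo_train(
    pool_signal: PoolSignal,
    pools: tuple[PoolParams, PoolParams],
    te: EchoTimes = EchoTimes(),
    offsets: HCMParams | None = None,
) -> EchoTrain:
    """Net magnitude echo train from pool-resolved TE = 0 amplitudes."""
    values = batch_echo_trains(
        np.array([pool_signal.s_mw]),
        np.array([pool_signal.s_ie]),
        pools,
        te,
        offsets,
    )[0]
    return EchoTrain(values, te, is_magnitude=True)


def batch_echo_trains(
    s_mw: np.ndarray,
    s_ie: np.ndarray,
    pools: tuple[PoolParams, PoolParams],
    te: EchoTimes = EchoTimes(),
    offsets: HCMParams | None = None,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised net magnitude trains; returns shape ``s_mw.shape + (n_echo,)``.

    ``theta`` (degrees, broadcastable to ``s_mw``) overrides the angle in
    ``offsets`` per element when given.
    """
    s_mw = np.asarray(s_mw, dtype=complex)
    s_ie = np.asarray(s_ie, dtype=complex)
    if not (np.all(np.isfinite(s_mw)) and np.all(np.isfinite(s_ie))):
        raise ValueError("pool amplitudes must be finite")
    pa, pb = pools
    te_ms = te.ms
    if offsets is None:
        dw_mw = dw_ie = np.zeros(s_mw.shape)
    elif theta is None:
        w_mw, w_ie = hcm_offsets(offsets.theta, offsets)
        dw_mw = np.full(s_mw.shape, w_mw)
        dw_ie = np.full(s_mw.shape, w_ie)
    else:
        theta = np.broadcast_to(np.asarray(theta, dtype=float), s_mw.shape)
        dw_mw, dw_ie = hcm_offsets(theta, offsets)
    # decay rates 1/ms; offsets rad/s -> rad/ms
    r_mw = 1.0 / pa.t2 + 1j * dw_mw[..., None] * 1e-3
    r_ie = 1.0 / pb.t2 + 1j * dw_ie[..., None] * 1e-3
    net = s_mw[..., None] * np.exp(-te_ms * r_mw) + s_ie[..., None] * np.exp(
        -te_ms * r_ie
    )
    return np.abs(net)


def add_complex_noise(
    train: EchoTrain,
    noise: NoiseModel,
    s_te0: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy magnitude instantiations of an echo train.

    Zero-mean Gaussian noise with standard deviation ``s_te0 / snr_te0`` is
    added independently to the real and imaginary channels (the magnitude
    train is treated as real) and the magnitude is taken, yielding Rician
    samples.  Returns shape ``(n_instantiations,) + train.values.shape``.
    Reproducible for a fixed ``noise.seed`` when ``rng`` is not supplied.
    """
    if s_te0 is None:
        raise ValueError("s_te0 (TE=0 reference amplitude) is required")
    if not s_te0 > 0:
        raise ValueError("s_te0 must be > 0")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    sigma = s_te0 / noise.snr_te0
    shape = (noise.n_instantiations,) + train.values.shape
    if sigma == 0.0 or not np.isfinite(sigma):
        return np.broadcast_to(train.values, shape).copy()
    re = train.values + sigma * rng.standard_normal(shape)
    im = sigma * rng.standard_normal(shape)
    return np.hypot(re, im)
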