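"""Brute-force isochromat oracle for the EPG-X SPGR simulator.

A dephasing ensemble of spins spanning one spoiler period is propagated
through the identical pulse train in the spatial domain: RF pulses are
applied as geometric rotations (via scipy's rotation classes), relaxation
and directional exchange advance each position's pool pair with the exact
Bloch-McConnell matrix exponential, the spoiler gradient is a per-position
phase ramp, and diffusion damps the spatial-frequency content of the
magnetisation profile with the exact constant-gradient attenuation.  The
ensemble mean of the transverse magnetisation is the net signal; the same
pseudo-steady-state contract as the EPG-X simulator applies.

This module shares no state-evolution code with :mod:`r2hat.epgx`; it is
the independent cross-check of that implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .epgx import ConvergenceError, PoolSignal, _propagators, _rates
from .params import ExchangeParams, PoolParams, SequenceParams

__all__ = ["isochromat_oracle"]


def isochromat_oracle(
    pools: tuple[PoolParams, PoolParams],
    exchange: ExchangeParams | None,
    seq: SequenceParams,
    flip_angle: float,
    n_isochromats: int = 10_000,
) -> PoolSignal:
    """Time-domain Bloch-McConnell reference simulation.

    ``n_isochromats`` positions are spread uniformly over one spoiler
    dephasing period (the ensemble average over the voxel equals the
    average over one period because the net dephasing is an integer number
    of turns).  Returns pool-resolved demodulated TE = 0 amplitudes averaged
    over the final RF-phase cycle, like the EPG-X simulator.
    """
    if n_isochromats < 1000:
        raise ValueError("n_isochromats must be >= 1000 for a faithful ensemble")
    if flip_angle == 0.0:
        return PoolSignal(0.0 + 0.0j, 0.0 + 0.0j, 0)

    t1, t2, frac, dw, ka, kb = _rates(pools, exchange)
    e_t, e_l, rec = _propagators(t1, t2, frac, dw, ka, kb, seq.tr)

    n = int(n_isochromats)
    # positions over one dephasing period; per-TR gradient phase ramp 0..2pi
    u = (np.arange(n) + 0.5) / n
    grad_phase = np.exp(1j * 2.0 * np.pi * u)

    # diffusion: spatial frequency of FFT bin m is m * dk where dk is the
    # dephasing per TR per unit length; exact b-factor for a constant
    # gradient advancing every component by one bin per TR
    use_diffusion = seq.diffusion_coefficient > 0 and not seq.ideal_spoiling
    if use_diffusion:
        d_mm2_per_ms = seq.diffusion_coefficient * 1e-6  # um^2/ms -> mm^2/ms
        dk = seq.spoiler_dephasing / seq.voxel_size  # rad/mm
        m = np.fft.fftfreq(n, d=1.0 / n)  # signed bin index
        scale = d_mm2_per_ms * dk * dk * seq.tr
        att_t = np.exp(-scale * (m * m + m + 1.0 / 3.0))
        att_z = np.exp(-scale * (m * m))

    # magnetisation per pool per position
    m_t = np.zeros((2, n), dtype=complex)  # Mx + i My
    m_z = np.tile(frac[:, None], (1, n)).astype(float)

    alpha = float(flip_angle)
    cycle = seq.rf_cycle_length if not seq.ideal_spoiling else 1
    inc = seq.rf_spoil_increment if not seq.ideal_spoiling else 0.0
    tol = seq.convergence_tol
    tiny = 1e-14

    s_cycle = np.zeros(2, dtype=complex)
    prev_mag: float | None = None
    last_rel = np.inf

    for pulse in range(int(seq.n_pulses_max)):
        phi_deg = 0.5 * inc * pulse * (pulse + 1) % 360.0
        axis = np.deg2rad(phi_deg)
        rot = Rotation.from_rotvec(
            np.deg2rad(alpha) * np.array([np.cos(axis), np.sin(axis), 0.0])
        ).as_matrix()
        mx, my = m_t.real, m_t.imag
        mx2 = rot[0, 0] * mx + rot[0, 1] * my + rot[0, 2] * m_z
        my2 = rot[1, 0] * mx + rot[1, 1] * my + rot[1, 2] * m_z
        mz2 = rot[2, 0] * mx + rot[2, 1] * my + rot[2, 2] * m_z
        m_t = mx2 + 1j * my2
        m_z = mz2

        demod = np.exp(-1j * axis)
        s_cycle += m_t.mean(axis=1) * demod

        if seq.ideal_spoiling:
            m_t[:] = 0.0
            m_z = e_l @ m_z + rec[:, None]
        else:
            m_t = e_t @ m_t
            m_z = e_l @ m_z + rec[:, None]
            if use_diffusion:
                f_t = np.fft.fft(m_t, axis=1)
                m_t = np.fft.ifft(f_t * att_t, axis=1)
                f_z = np.fft.fft(m_z, axis=1)
                m_z = np.real(np.fft.ifft(f_z * att_z, axis=1))
            m_t = m_t * grad_phase

        if (pulse + 1) % cycle == 0:
            avg = s_cycle / cycle
            mag = float(abs(avg[0] + avg[1]))
            if prev_mag is not None:
                denom = max(prev_mag, tiny)
                rel = abs(mag - prev_mag) / denom
                if mag < tiny and prev_mag < tiny:
                    rel = 0.0
                last_rel = rel
                if rel < tol:
                    return PoolSignal(complex(avg[0]), complex(avg[1]), pulse + 1)
            prev_mag = mag
            s_cycle[:] = 0.0

    raise ConvergenceError(
        f"isochromat ensemble did not reach pseudo-steady state within "
        f"{seq.n_pulses_max} pulses (last relative change {last_rel:.3e}, "
        f"tolerance {tol:.1e})",
        float(last_rel),
    )
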