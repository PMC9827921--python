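"""Parameter containers and protocol constants.

Times are milliseconds throughout the package; angles are degrees at every
public interface (radians only inside numerical kernels); relaxation rates
are reported in 1/s.  Signals are normalised so that the total equilibrium
magnetisation is M0 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

__all__ = [
    "PoolParams",
    "ExchangeParams",
    "SequenceParams",
    "EchoTimes",
    "HCMParams",
    "NoiseModel",
    "PAPER_TES_MS",
    "PAPER_ALPHAS_DEG",
    "ALPHA_SETS",
    "MWF_GRID",
    "RESIDENCY_GRID_MS",
    "MW_POOL",
    "IE_POOL",
    "MWF_WM",
    "MWF_GM",
    "two_pool_wm",
]

#: Multi-echo readout of the protocol: 6 echoes, 2.56 ms first echo, 2.38 ms
#: spacing (2.56:2.38:14.46 ms).
PAPER_TES_MS = tuple(np.round(2.56 + 2.38 * np.arange(6), 2))

#: Nominal excitation flip angles of the variable-flip-angle protocol.
PAPER_ALPHAS_DEG = (6.0, 9.0, 12.0, 15.0, 19.0, 26.0, 31.0, 36.0, 42.0)

#: Flip-angle subsets used in the robustness analysis (set 1 = full protocol,
#: set 5 = the minimal PD/T1-weighted pair typical of MPM protocols).
ALPHA_SETS = {
    1: (6.0, 9.0, 12.0, 15.0, 19.0, 26.0, 31.0, 36.0, 42.0),
    2: (6.0, 9.0, 15.0, 26.0, 31.0, 42.0),
    3: (6.0, 9.0, 26.0, 42.0),
    4: (6.0, 26.0, 42.0),
    5: (6.0, 26.0),
}

#: Myelin-water-fraction grid of the tissue-condition sweep.
MWF_GRID = tuple(np.round(np.arange(0.02, 0.2001, 0.02), 2))

#: Myelin-water residency-time grid (directional MW -> IE), ms.
RESIDENCY_GRID_MS = (100.0, 200.0, 300.0, 400.0, 500.0)

MWF_WM = 0.16
MWF_GM = 0.06


@dataclass(frozen=True)
class PoolParams:
    """Relaxation parameters of one water pool.

    t1, t2 in ms; ``fraction`` is the equilibrium magnetisation fraction of
    the pool; ``delta_omega`` an optional bulk off-resonance (rad/s).
    """

    t1: float
    t2: float
    fraction: float
    delta_omega: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t1 > self.t2 > 0):
            raise ValueError(f"require t1 > t2 > 0, got t1={self.t1}, t2={self.t2}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")


#: Literature relaxation times of the two pools (myelin water / intra- and
#: extra-cellular water); fractions are placeholders replaced per condition.
MW_POOL = PoolParams(t1=280.0, t2=8.0, fraction=MWF_WM)
IE_POOL = PoolParams(t1=1450.0, t2=36.0, fraction=1.0 - MWF_WM)


@dataclass(frozen=True)
class ExchangeParams:
    """Directional exchange between myelin water (MW) and IE water.

    ``residency_time_mw`` is the mean time a spin spends in the MW pool
    before transferring to IE (ms).  The reverse rate follows from detailed
    balance, k_ie->mw = k_mw->ie * f_mw / f_ie, so the equilibrium net flux
    is zero to machine precision.
    """

    residency_time_mw: float

    def __post_init__(self) -> None:
        if not self.residency_time_mw > 0:
            raise ValueError("residency_time_mw must be > 0")

    @property
    def k_mw_to_ie(self) -> float:
        """Forward rate, 1/ms."""
        return 1.0 / self.residency_time_mw

    def k_ie_to_mw(self, fraction_mw: float, fraction_ie: float) -> float:
        """Reverse rate from detailed balance, 1/ms."""
        if fraction_ie <= 0.0:
            return 0.0
        return self.k_mw_to_ie * fraction_mw / fraction_ie


@dataclass(frozen=True)
class SequenceParams:
    """Spoiled gradient-echo sequence and spoiling model.

    ``spoiler_dephasing`` is the net gradient dephasing across one voxel per
    TR (radians, 6*pi for this protocol).  ``diffusion_coefficient`` and
    ``voxel_size`` set the strength of diffusion damping of high-order
    configuration states; the protocol source does not state them, so they
    are configuration defaults, not literature facts.
    """

    tr: float = 19.5
    flip_angles: tuple = PAPER_ALPHAS_DEG
    rf_spoil_increment: float = 144.0
    spoiler_dephasing: float = 6.0 * np.pi
    diffusion_coefficient: float = 1.0  # um^2/ms
    voxel_size: float = 1.0  # mm
    n_pulses_max: int = 2000
    convergence_tol: float = 1e-6
    max_state_order: int = 30
    ideal_spoiling: bool = False

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError("tr must be > 0")
        for a in self.flip_angles:
            if not (0.0 < a <= 90.0):
                raise ValueError(f"flip angles must lie in (0, 90] deg, got {a}")
        if not (0.0 <= self.rf_spoil_increment < 360.0):
            raise ValueError("rf_spoil_increment must be in [0, 360) deg")

    @property
    def rf_cycle_length(self) -> int:
        """Length of the effective RF-phase cycle (pulses).

        For a quadratic schedule phi_n = inc*n*(n+1)/2 the phases modulo
        360 deg repeat with period 360/gcd(inc, 360) at most; the 144 deg
        increment has a short period of 5 pulses.  Falls back to 5 for
        increments whose exact period exceeds 50.
        """
        inc = self.rf_spoil_increment
        if inc == 0.0:
            return 1
        # brute-force the period of phi_n mod 360 (quadratic schedules are
        # periodic whenever inc is rational in degrees)
        n = np.arange(0, 4000)
        phi = (0.5 * inc * n * (n + 1)) % 360.0
        for p in range(1, 51):
            if np.allclose(phi[p : 2000 + p], phi[:2000]):
                return p
        return 5


@dataclass(frozen=True)
class EchoTimes:
    """Strictly increasing echo times in ms."""

    te_list: tuple = PAPER_TES_MS

    def __post_init__(self) -> None:
        te = np.asarray(self.te_list, dtype=float)
        if te.ndim != 1 or te.size == 0:
            raise ValueError("te_list must be a non-empty 1-D sequence")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")

    @property
    def ms(self) -> np.ndarray:
        return np.asarray(self.te_list, dtype=float)

    @property
    def seconds(self) -> np.ndarray:
        return self.ms * 1e-3


# gyromagnetic ratio of 1H times 2*pi, rad/s/T
_GAMMA_RAD_PER_S_PER_T = 2.0 * np.pi * 42.576e6


@dataclass(frozen=True)
class HCMParams:
    """Hollow-cylinder fiber-model frequency offsets.

    The myelin sheath is modelled as a hollow cylinder with isotropic
    (``chi_iso``) and anisotropic (``chi_aniso``) magnetic susceptibility
    (ppm) relative to the water compartments, inner/outer radius ratio
    ``g_ratio``, and a chemical-exchange frequency term ``e_term`` (ppm).
    ``intra_axonal_weight`` is the fraction of the merged IE pool that sees
    the intra-axonal offset (the extra-axonal mean offset is zero).  The
    angular dependence of both compartment offsets enters only via sin^2 of
    the fiber-to-B0 angle theta.
    """

    theta: float = 0.0  # degrees
    chi_iso: float = -0.10  # ppm
    chi_aniso: float = -0.10  # ppm
    g_ratio: float = 0.8
    e_term: float = 0.02  # ppm
    intra_axonal_weight: float = 0.5
    b0: float = 7.0  # tesla

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 90.0):
            raise ValueError("theta must lie in [0, 90] degrees")
        if not (0.0 < self.g_ratio < 1.0):
            raise ValueError("g_ratio must lie in (0, 1)")

    def with_theta(self, theta: float) -> "HCMParams":
        return replace(self, theta=float(theta))

    def offsets(self) -> tuple[float, float]:
        """(delta_omega_mw, delta_omega_ie) in rad/s at this theta."""
        from .signal_model import hcm_offsets

        return hcm_offsets(self.theta, self)

    @property
    def gamma_b0(self) -> float:
        """omega0 in rad/s (per unit, multiply ppm values by 1e-6)."""
        return _GAMMA_RAD_PER_S_PER_T * self.b0


@dataclass(frozen=True)
class NoiseModel:
    """Complex Gaussian noise added to the echo train before magnitude."""

    snr_te0: float = 50.0
    n_instantiations: int = 10_000
    seed: int = 0
    #: how the noise standard deviation is referenced: "per-train" divides
    #: each train's own TE=0 amplitude by snr_te0 (keeps SNR constant across
    #: flip angle); "global-max" uses the largest TE=0 amplitude in a batch.
    reference: str = "per-train"

    def __post_init__(self) -> None:
        if not self.snr_te0 > 0:
            raise ValueError("snr_te0 must be > 0")
        if self.n_instantiations < 1:
            raise ValueError("n_instantiations must be >= 1")
        if self.reference not in ("per-train", "global-max"):
            raise ValueError("reference must be 'per-train' or 'global-max'")


def two_pool_wm(mwf: float = MWF_WM) -> tuple[PoolParams, PoolParams]:
    """The literature two-pool model at a given myelin water fraction."""
    return (
        replace(MW_POOL, fraction=float(mwf)),
        replace(IE_POOL, fraction=1.0 - float(mwf)),
    )
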