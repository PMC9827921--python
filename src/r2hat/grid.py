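"""Tissue-condition grid simulations and the flip-angle-set analyses.

The condition grid sweeps myelin water fraction (0.02-0.20, step 0.02) and
MW residency time (100-500 ms, step 100) at the protocol's nine flip
angles, yielding pool-resolved steady-state amplitudes per condition.  The
helpers here turn those amplitudes into echo trains, per-alpha R2* values,
linear-flip-angle-model components and the error/sensitivity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epgx import simulate_spgr_batch
from .fits import AlphaLinearModel, LogLinearR2Star
from .metrics import rms_percent, rmse_over_conditions, sensitivity_max_variation
from .params import (
    ALPHA_SETS,
    IE_POOL,
    MW_POOL,
    MWF_GRID,
    PAPER_ALPHAS_DEG,
    RESIDENCY_GRID_MS,
    EchoTimes,
    HCMParams,
    NoiseModel,
    SequenceParams,
)
from .signal_model import batch_echo_trains

__all__ = [
    "ConditionGrid",
    "simulate_grid",
    "linear_model_components",
    "alpha_set_errors",
    "alpha_set_summary",
    "noisy_alpha_set_summary",
    "component_sensitivities",
]


@dataclass
class ConditionGrid:
    """Pool amplitudes over a rectangular (MWF x residency x alpha) grid."""

    mwf: np.ndarray  # (n_mwf,)
    residency_ms: np.ndarray  # (n_res,)
    alphas_deg: np.ndarray  # (n_alpha,)
    s_mw: np.ndarray  # complex (n_mwf, n_res, n_alpha)
    s_ie: np.ndarray  # complex (n_mwf, n_res, n_alpha)
    seq: SequenceParams = field(default_factory=SequenceParams)

    def __post_init__(self) -> None:
        shape = (self.mwf.size, self.residency_ms.size, self.alphas_deg.size)
        if self.s_mw.shape != shape or self.s_ie.shape != shape:
            raise ValueError("amplitude arrays do not match the grid shape")

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with one row per (mwf, residency, flip angle)."""
        m, r, a = np.meshgrid(
            self.mwf, self.residency_ms, self.alphas_deg, indexing="ij"
        )
        return pd.DataFrame(
            {
                "mwf": m.ravel(),
                "residency_ms": r.ravel(),
                "flip_deg": a.ravel(),
                "s_mw_re": self.s_mw.real.ravel(),
                "s_mw_im": self.s_mw.imag.ravel(),
                "s_ie_re": self.s_ie.real.ravel(),
                "s_ie_im": self.s_ie.imag.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seq: SequenceParams | None = None):
        mwf = np.unique(df["mwf"].to_numpy())
        res = np.unique(df["residency_ms"].to_numpy())
        al = np.unique(df["flip_deg"].to_numpy())
        shape = (mwf.size, res.size, al.size)
        if len(df) != np.prod(shape):
            raise ValueError("table is not a complete rectangular grid")
        df = df.sort_values(["mwf", "residency_ms", "flip_deg"])
        s_mw = (df["s_mw_re"] + 1j * df["s_mw_im"]).to_numpy().reshape(shape)
        s_ie = (df["s_ie_re"] + 1j * df["s_ie_im"]).to_numpy().reshape(shape)
        return cls(mwf, res, al, s_mw, s_ie, seq or SequenceParams())

    # -- forward model -----------------------------------------------------

    def echo_trains(
        self,
        te: EchoTimes = EchoTimes(),
        hcm: HCMParams | None = None,
    ) -> np.ndarray:
        """Noise-free magnitude trains, shape (n_mwf, n_res, n_alpha, n_echo)."""
        pools = (MW_POOL, IE_POOL)  # only T2s are used here
        return batch_echo_trains(self.s_mw, self.s_ie, pools, te, hcm)

    def r2star(
        self, te: EchoTimes = EchoTimes(), hcm: HCMParams | None = None
    ) -> np.ndarray:
        """Per-alpha mono-exponential R2* (1/s), shape (n_mwf, n_res, n_alpha)."""
        trains = self.echo_trains(te, hcm)
        return LogLinearR2Star().fit(te, trains).r2star_


def simulate_grid(
    mwf_grid=MWF_GRID,
    residency_grid_ms=RESIDENCY_GRID_MS,
    alphas_deg=PAPER_ALPHAS_DEG,
    seq: SequenceParams | None = None,
) -> ConditionGrid:
    """EPG-X steady state over the full tissue-condition grid (batched)."""
    seq = seq or SequenceParams()
    mwf = np.asarray(mwf_grid, dtype=float)
    res = np.asarray(residency_grid_ms, dtype=float)
    al = np.asarray(alphas_deg, dtype=float)
    mm, rr, aa = np.meshgrid(mwf, res, al, indexing="ij")
    b = mm.size
    t1 = np.broadcast_to([MW_POOL.t1, IE_POOL.t1], (b, 2))
    t2 = np.broadcast_to([MW_POOL.t2, IE_POOL.t2], (b, 2))
    frac = np.stack([mm.ravel(), 1.0 - mm.ravel()], axis=1)
    dw = np.zeros((b, 2))
    kf = 1.0 / rr.ravel()
    sig, _ = simulate_spgr_batch(t1, t2, frac, dw, kf, aa.ravel(), seq)
    shape = mm.shape
    return ConditionGrid(
        mwf, res, al, sig[:, 0].reshape(shape), sig[:, 1].reshape(shape), seq
    )


def linear_model_components(
    r2: np.ndarray,
    alphas_deg,
    fit_alphas=None,
    eval_alphas=None,
):
    """Fit the linear flip-angle model per condition and evaluate residuals.

    ``r2``: per-alpha R2* with the alpha axis last, matching ``alphas_deg``.
    ``fit_alphas`` selects the subset used for fitting (default all);
    residuals are evaluated at ``eval_alphas`` (default all supplied
    angles).  Returns ``(r2star_hat, slope, eps)`` where ``eps`` has the
    evaluation-alpha axis last.
    """
    alphas = np.asarray(alphas_deg, dtype=float)
    fit_alphas = alphas if fit_alphas is None else np.asarray(fit_alphas, dtype=float)
    eval_alphas = alphas if eval_alphas is None else np.asarray(eval_alphas, dtype=float)
    fit_idx = [int(np.argmin(np.abs(alphas - a))) for a in fit_alphas]
    if np.max(np.abs(alphas[fit_idx] - fit_alphas)) > 1e-9:
        raise ValueError("fit_alphas must be a subset of alphas_deg")
    eval_idx = [int(np.argmin(np.abs(alphas - a))) for a in eval_alphas]
    if np.max(np.abs(alphas[eval_idx] - eval_alphas)) > 1e-9:
        raise ValueError("eval_alphas must be a subset of alphas_deg")
    model = AlphaLinearModel().fit(alphas[fit_idx], r2[..., fit_idx])
    recon = model.predict(alphas[eval_idx])
    eps = r2[..., eval_idx] - recon
    return model.r2star_hat_, model.dr2star_dalpha_, eps


def alpha_set_errors(r2: np.ndarray, alphas_deg, alpha_set):
    """Per-alpha RMSE and RMS%% across conditions for one flip-angle set.

    The model is fitted on ``alpha_set`` and residuals are evaluated at all
    supplied angles; returns ``(rmse, rms_pct)`` arrays over the evaluation
    angles.
    """
    _, _, eps = linear_model_components(r2, alphas_deg, fit_alphas=alpha_set)
    n_alpha = eps.shape[-1]
    flat_eps = eps.reshape(-1, n_alpha)
    flat_r2 = r2.reshape(-1, n_alpha)
    rmse = np.array([rmse_over_conditions(flat_eps[:, j]) for j in range(n_alpha)])
    pct = np.array(
        [rms_percent(flat_eps[:, j], flat_r2[:, j]) for j in range(n_alpha)]
    )
    return rmse, pct


def alpha_set_summary(
    r2: np.ndarray, alphas_deg, sets: dict | None = None
) -> pd.DataFrame:
    """Noise-free RMSE / RMS%% per flip-angle set (mean over the 9 angles)."""
    sets = sets or ALPHA_SETS
    rows = []
    for name, subset in sets.items():
        rmse, pct = alpha_set_errors(r2, alphas_deg, subset)
        rows.append(
            {
                "alpha_set": name,
                "n_alphas": len(subset),
                "rmse_mean": rmse.mean(),
                "rmse_max": rmse.max(),
                "rms_pct_mean": pct.mean(),
                "rms_pct_max": pct.max(),
            }
        )
    return pd.DataFrame(rows)


def noisy_alpha_set_summary(
    grid: ConditionGrid,
    te: EchoTimes = EchoTimes(),
    noise: NoiseModel = NoiseModel(),
    sets: dict | None = None,
    chunk: int = 100,
) -> pd.DataFrame:
    """Monte-Carlo flip-angle-set errors under complex noise.

    Per instantiation, noisy magnitude trains are fitted per alpha, the
    linear model is fitted on each alpha set, residuals are evaluated at
    all nine angles, and the across-condition RMSE / RMS%% is averaged over
    angles.  The percentage error is referenced to the same per-
    instantiation noisy per-alpha R2* that defines the residual (the
    simulated R2* under noise).  Returns the mean and standard deviation
    across instantiations per set.  The noise standard deviation follows
    ``noise.reference``: each train's own TE=0 amplitude (default) or the
    batch maximum.
    """
    sets = sets or ALPHA_SETS
    clean = grid.echo_trains(te)  # (m, r, a, e)
    m_n, r_n, a_n, e_n = clean.shape
    s_te0 = np.abs(grid.s_mw + grid.s_ie)
    if noise.reference == "global-max":
        sigma = np.full_like(s_te0, s_te0.max() / noise.snr_te0)
    else:
        sigma = s_te0 / noise.snr_te0
    rng = np.random.default_rng(noise.seed)
    alphas = grid.alphas_deg

    acc = {name: {"rmse": [], "pct": []} for name in sets}
    remaining = noise.n_instantiations
    while remaining > 0:
        n_i = min(chunk, remaining)
        remaining -= n_i
        shape = (n_i,) + clean.shape
        re = clean + sigma[..., None] * rng.standard_normal(shape)
        im = sigma[..., None] * rng.standard_normal(shape)
        noisy = np.hypot(re, im)
        r2n = LogLinearR2Star().fit(te, noisy).r2star_  # (n_i, m, r, a)
        for name, subset in sets.items():
            _, _, eps = linear_model_components(r2n, alphas, fit_alphas=subset)
            flat = eps.reshape(n_i, -1, a_n)
            ref = r2n.reshape(n_i, -1, a_n)
            rmse = np.sqrt(np.mean(flat**2, axis=1)).mean(axis=-1)
            pct = np.sqrt(np.mean((100.0 * flat / ref) ** 2, axis=1)).mean(axis=-1)
            acc[name]["rmse"].append(rmse)
            acc[name]["pct"].append(pct)

    rows = []
    for name, subset in sets.items():
        rmse = np.concatenate(acc[name]["rmse"])
        pct = np.concatenate(acc[name]["pct"])
        rows.append(
            {
                "alpha_set": name,
                "n_alphas": len(subset),
                "rmse_mean": rmse.mean(),
                "rmse_std": rmse.std(ddof=1),
                "rms_pct_mean": pct.mean(),
                "rms_pct_std": pct.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def component_sensitivities(r2: np.ndarray, alphas_deg) -> dict:
    """Maximum-variation-over-mean (percent) of both model components.

    ``r2`` must be the (n_mwf, n_res, n_alpha) noise-free grid.  Returns the
    four summaries: sensitivity of the intercept R2*^ and of the slope
    dR2*/dalpha to the MWF axis and to the residency axis.
    """
    r2hat, slope, _ = linear_model_components(r2, alphas_deg)
    return {
        "r2star_hat_mwf": sensitivity_max_variation(r2hat, axis=0),
        "r2star_hat_residency": sensitivity_max_variation(r2hat, axis=1),
        "slope_mwf": sensitivity_max_variation(slope, axis=0),
        "slope_residency": sensitivity_max_variation(slope, axis=1),
    }
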