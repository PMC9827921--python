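"""R2* estimators.

Four estimators cover the mono-exponential analysis chain:

* :class:`LogLinearR2Star` — per-acquisition log-linear fit of ln(S)
  against TE (ordinary least squares, unweighted).
* :class:`EstaticsR2Star` — joint fit across several flip-angle
  acquisitions with one shared decay rate and per-acquisition intercepts
  (the ESTATICS model).
* :class:`AlphaLinearModel` — the linear flip-angle model
  R2*(alpha) = R2*^ + (dR2*/dalpha) * alpha_eff that partitions R2* into a
  flip-angle-independent intercept and a flip-angle-dependent slope, with
  the effective angle alpha_eff = nominal alpha x B1+ efficiency.
* :class:`MWFQuadratic` — the origin-constrained quadratic model
  dR2*/dalpha = beta1*MWF + beta2*MWF^2 and its inversion to an MWF
  estimate.

All estimators follow scikit-learn conventions (``fit`` / ``predict``,
``get_params``, fitted attributes with a trailing underscore) and broadcast
over arbitrary leading axes so a voxel grid fits in one call.  Rates are
reported in 1/s (echo times are supplied in ms and converted internally);
flip angles enter in degrees, so slopes are 1/s per degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .params import EchoTimes
from .signal_model import EchoTrain

__all__ = [
    "LogLinearR2Star",
    "EstaticsR2Star",
    "AlphaLinearModel",
    "MWFQuadratic",
    "R2StarFit",
    "EstaticsFit",
    "AlphaLinearFit",
    "fit_loglinear_r2star",
    "fit_estatics",
    "fit_alpha_linear_model",
    "fit_mwf_quadratic",
    "invert_mwf",
]


# ---------------------------------------------------------------------------
# result records


@dataclass(frozen=True)
class R2StarFit:
    r2star: float  # 1/s
    ln_s0: float
    rss: float
    n_excluded: int = 0


@dataclass(frozen=True)
class EstaticsFit:
    r2star_common: float  # 1/s
    intercepts: tuple  # ln S0 per flip-angle dataset


@dataclass(frozen=True)
class AlphaLinearFit:
    r2star_hat: float  # 1/s
    dr2star_dalpha: float  # 1/s per degree
    residuals: tuple  # per flip angle, 1/s


# ---------------------------------------------------------------------------
# shared masked-OLS sums


def _te_seconds(te) -> np.ndarray:
    if isinstance(te, EchoTimes):
        return te.seconds
    return np.asarray(te, dtype=float) * 1e-3


def _log_sums(values: np.ndarray, te_s: np.ndarray, floor: float):
    """Masked first and second moments for the log-linear regression."""
    mask = values > floor
    safe = np.where(mask, values, 1.0)
    y = np.where(mask, np.log(safe), 0.0)
    w = mask.astype(float)
    x = te_s
    sw = w.sum(axis=-1)
    sx = (w * x).sum(axis=-1)
    sxx = (w * x * x).sum(axis=-1)
    sy = (w * y).sum(axis=-1)
    sxy = (w * x * y).sum(axis=-1)
    return mask, y, sw, sx, sxx, sy, sxy


class LogLinearR2Star(BaseEstimator):
    """Per-acquisition log-linear R2* fit.

    Samples at or below ``positivity_floor`` are excluded from the log
    (they cannot occur for magnitude data; the floor guards synthetic edge
    cases).  No Rician bias correction is applied, matching standard
    toolbox behaviour.  Inputs with fewer than two usable echoes raise for
    scalar fits and are marked NaN in array fits.
    """

    def __init__(self, positivity_floor: float = 1e-12):
        self.positivity_floor = positivity_floor

    def fit(self, te, values):
        """``te`` in ms (or :class:`EchoTimes`); ``values`` (..., n_echo)."""
        te_s = _te_seconds(te)
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != te_s.size:
            raise ValueError("values and te have mismatched echo counts")
        if te_s.size < 2:
            raise ValueError("at least 2 echoes are required")
        mask, y, sw, sx, sxx, sy, sxy = _log_sums(values, te_s, self.positivity_floor)
        with np.errstate(divide="ignore", invalid="ignore"):
            den = sxx - sx * sx / sw
            num = sxy - sx * sy / sw
            slope = np.asarray(num / den)
            intercept = np.asarray((sy - slope * sx) / sw)
        bad = (sw < 2) | ~np.isfinite(slope)
        if np.ndim(bad) == 0:
            if bad:
                raise ValueError(
                    f"only {int(sw)} usable echoes above the positivity floor"
                )
        else:
            slope = np.where(bad, np.nan, slope)
            intercept = np.where(bad, np.nan, intercept)
        resid = np.where(mask, y - intercept[..., None] - slope[..., None] * te_s, 0.0)
        self.r2star_ = -slope
        self.ln_s0_ = intercept
        self.rss_ = (resid * resid).sum(axis=-1)
        self.n_excluded_ = (~mask).sum(axis=-1)
        return self

    def predict(self, te):
        te_s = _te_seconds(te)
        return np.exp(self.ln_s0_[..., None] - self.r2star_[..., None] * te_s)


class EstaticsR2Star(BaseEstimator):
    """Joint log-linear fit with one shared decay across acquisitions.

    Pools the multi-echo data of each flip-angle acquisition, estimating a
    common R2* and one ln(S0) intercept per acquisition; for a single
    acquisition this reduces exactly (bit for bit) to
    :class:`LogLinearR2Star`.
    """

    def __init__(self, positivity_floor: float = 1e-12):
        self.positivity_floor = positivity_floor

    def fit(self, te_list, values_list):
        """``te_list``: per-acquisition echo times (ms); ``values_list``:
        matching sequence of arrays, each (..., n_echo_a)."""
        if len(values_list) < 1:
            raise ValueError("at least one acquisition is required")
        if len(te_list) != len(values_list):
            raise ValueError("te_list and values_list lengths differ")
        num = 0.0
        den = 0.0
        per = []
        for te, values in zip(te_list, values_list):
            te_s = _te_seconds(te)
            values = np.asarray(values, dtype=float)
            if values.shape[-1] != te_s.size:
                raise ValueError("values and te have mismatched echo counts")
            mask, y, sw, sx, sxx, sy, sxy = _log_sums(
                values, te_s, self.positivity_floor
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                num = num + (sxy - sx * sy / sw)
                den = den + (sxx - sx * sx / sw)
            per.append((sw, sx, sy))
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = num / den
        usable = sum(p[0] for p in per)
        bad = ~np.isfinite(slope) | (usable < len(per) + 1)
        if np.ndim(bad) == 0:
            if bad:
                raise ValueError("not enough usable echoes for a joint fit")
        else:
            slope = np.where(bad, np.nan, slope)
        intercepts = []
        for sw, sx, sy in per:
            with np.errstate(divide="ignore", invalid="ignore"):
                intercepts.append((sy - slope * sx) / sw)
        self.r2star_ = -slope
        self.ln_s0_ = intercepts
        return self


class AlphaLinearModel(BaseEstimator):
    """Linear partition of R2* into flip-angle-independent and -dependent
    components.

    Fits R2*(alpha) = intercept + slope * alpha_eff by least squares, where
    alpha_eff = alpha * b1 (B1+ efficiency, dimensionless multiplier of the
    nominal angle; maps supplied in percent are normalised by the caller).
    """

    def fit(self, alphas_deg, r2stars, b1=None):
        """``alphas_deg``: (n_alpha,); ``r2stars``: (..., n_alpha) in 1/s;
        ``b1``: scalar or (...) per-sample efficiency (default 1)."""
        alphas = np.asarray(alphas_deg, dtype=float)
        y = np.asarray(r2stars, dtype=float)
        if alphas.ndim != 1 or alphas.size < 2:
            raise ValueError("need at least 2 flip angles")
        if y.shape[-1] != alphas.size:
            raise ValueError("r2stars and alphas have mismatched lengths")
        if b1 is None:
            b1 = 1.0
        b1 = np.asarray(b1, dtype=float)
        if np.any(b1 <= 0) or not np.all(np.isfinite(b1)):
            raise ValueError("B1 efficiency must be positive and finite")
        x = alphas * b1[..., None]
        n = float(alphas.size)
        valid = np.isfinite(y)
        w = valid.astype(float)
        yz = np.where(valid, y, 0.0)
        sw = w.sum(axis=-1)
        sx = (w * x).sum(axis=-1)
        sxx = (w * x * x).sum(axis=-1)
        sy = yz.sum(axis=-1)
        sxy = (w * x * yz).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            den = sxx - sx * sx / sw
            slope = np.asarray((sxy - sx * sy / sw) / den)
            intercept = np.asarray((sy - slope * sx) / sw)
        degenerate = ~(den > np.finfo(float).eps * np.maximum(sxx, 1.0)) | (sw < 2)
        if np.ndim(degenerate) == 0:
            if degenerate:
                raise ValueError("fewer than 2 distinct effective flip angles")
        else:
            slope = np.where(degenerate, np.nan, slope)
            intercept = np.where(degenerate, np.nan, intercept)
        self.r2star_hat_ = intercept
        self.dr2star_dalpha_ = slope
        self.residuals_ = np.where(valid, y - (intercept[..., None] + slope[..., None] * x), np.nan)
        self.alphas_ = alphas
        return self

    def predict(self, alphas_deg, b1=None):
        alphas = np.asarray(alphas_deg, dtype=float)
        if b1 is None:
            b1 = 1.0
        x = alphas * np.asarray(b1, dtype=float)[..., None]
        return self.r2star_hat_[..., None] + self.dr2star_dalpha_[..., None] * x


class MWFQuadratic(BaseEstimator):
    """Origin-constrained quadratic dependence of dR2*/dalpha on MWF."""

    def fit(self, mwf, slopes):
        x = np.asarray(mwf, dtype=float)
        y = np.asarray(slopes, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("need at least 2 grid points")
        design = np.stack([x, x * x], axis=1)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.beta1_, self.beta2_ = float(beta[0]), float(beta[1])
        return self

    def predict(self, mwf):
        x = np.asarray(mwf, dtype=float)
        return self.beta1_ * x + self.beta2_ * x * x

    def invert(self, slope: float, mwf_max: float = 0.5) -> float:
        """MWF estimate from a measured slope: the root of
        beta2*x^2 + beta1*x - slope in [0, mwf_max]."""
        b1, b2 = self.beta1_, self.beta2_
        if b2 == 0.0:
            if b1 == 0.0:
                raise ValueError("degenerate model: both coefficients are zero")
            root = slope / b1
        else:
            disc = b1 * b1 + 4.0 * b2 * slope
            if disc < 0:
                raise ValueError(
                    f"no real root: discriminant {disc:.3g} < 0 for slope {slope:.3g}"
                )
            roots = [(-b1 + s * np.sqrt(disc)) / (2.0 * b2) for s in (+1.0, -1.0)]
            in_range = [r for r in roots if 0.0 <= r <= mwf_max]
            if not in_range:
                raise ValueError(
                    f"no root in [0, {mwf_max}]: candidates {roots} for slope {slope:.3g}"
                )
            root = min(in_range)
        if not (0.0 <= root <= mwf_max):
            raise ValueError(f"inverted MWF {root:.3g} outside [0, {mwf_max}]")
        return float(root)


# ---------------------------------------------------------------------------
# functional wrappers (spec-level operations)


def fit_loglinear_r2star(train: EchoTrain) -> R2StarFit:
    est = LogLinearR2Star().fit(train.te, train.values)
    return R2StarFit(
        r2star=float(est.r2star_),
        ln_s0=float(est.ln_s0_),
        rss=float(est.rss_),
        n_excluded=int(est.n_excluded_),
    )


def fit_estatics(trains: list[EchoTrain]) -> EstaticsFit:
    est = EstaticsR2Star().fit([t.te for t in trains], [t.values for t in trains])
    return EstaticsFit(
        r2star_common=float(est.r2star_),
        intercepts=tuple(float(i) for i in est.ln_s0_),
    )


def fit_alpha_linear_model(r2stars, alphas, b1: float = 1.0) -> AlphaLinearFit:
    est = AlphaLinearModel().fit(alphas, r2stars, b1)
    return AlphaLinearFit(
        r2star_hat=float(est.r2star_hat_),
        dr2star_dalpha=float(est.dr2star_dalpha_),
        residuals=tuple(np.asarray(est.residuals_, dtype=float)),
    )


def fit_mwf_quadratic(slopes, mwf_grid) -> MWFQuadratic:
    return MWFQuadratic().fit(mwf_grid, slopes)


def invert_mwf(model: MWFQuadratic, slope: float) -> float:
    return model.invert(slope)
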