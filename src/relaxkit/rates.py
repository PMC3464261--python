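"""Extraction of R1, R2 and heteronuclear NOE from peak intensities.

Cross-peak volumes are integrated over a small ellipse around each peak
center (averaging noise while staying on the crest of the peak), decay
series are fitted to a two-parameter single exponential with Monte-Carlo
error estimates, and transverse rates are recovered from spin-lock
(R1rho) measurements through the tilt-angle relation

    R1rho = R1 cos^2(theta) + R2eff sin^2(theta),

where theta = arctan(omega1 / delta_omega) is the angle between the
effective field and the static field, omega1 the spin-lock strength and
delta_omega the resonance offset.  On resonance theta = 90 deg and R1rho
is R2eff directly.  R2eff still contains any exchange contribution; its
separation is the model-free stage's job.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "PeakGrid",
    "DecaySeries",
    "RateEstimate",
    "SpinLockGeometry",
    "integrate_ellipse",
    "ExponentialRateFitter",
    "fit_exponential",
    "r2_from_r1rho",
    "hetero_noe",
]


@dataclass
class PeakGrid:
    """2D spectrum surface: values[i, j] at (h_axis[i], n_axis[j]) in Hz."""

    values: np.ndarray
    h_axis: np.ndarray
    n_axis: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.h_axis = np.asarray(self.h_axis, dtype=float)
        self.n_axis = np.asarray(self.n_axis, dtype=float)
        if self.values.shape != (self.h_axis.size, self.n_axis.size):
            raise ValueError("grid shape does not match axis lengths")
        for ax in (self.h_axis, self.n_axis):
            d = np.diff(ax)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("grid axes must be strictly monotonic")


@dataclass(frozen=True)
class DecaySeries:
    """One residue's peak volumes versus relaxation delay."""

    residue_index: int
    delays: tuple[float, ...]  # seconds
    volumes: tuple[float, ...]
    sigma: float = 0.0  # noise sd on volumes; 0 = estimate from fit residuals

    def __post_init__(self) -> None:
        object.__setattr__(self, "delays", tuple(float(d) for d in self.delays))
        object.__setattr__(self, "volumes", tuple(float(v) for v in self.volumes))
        if len(self.delays) != len(self.volumes):
            raise ValueError("delays and volumes must have equal length")
        if len(self.delays) < 3:
            raise ValueError("need at least 3 points to fit a decay")
        if any(d <= 0 for d in self.delays):
            raise ValueError("delays must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class RateEstimate:
    """Fitted decay rate with Monte-Carlo error."""

    rate: float
    rate_error: float
    amplitude: float
    n_mc: int
    negative_rate: bool = False

    def __post_init__(self) -> None:
        if self.rate_error < 0:
            raise ValueError("rate_error must be non-negative")


@dataclass(frozen=True)
class SpinLockGeometry:
    """Spin-lock field strength and offset (both Hz) defining the tilt angle."""

    omega1: float
    delta_omega: float = 0.0

    def __post_init__(self) -> None:
        if self.omega1 <= 0:
            raise ValueError("spin-lock strength omega1 must be positive")

    @property
    def theta(self) -> float:
        """Tilt angle in radians, in (0, pi/2]; pi/2 on resonance."""
        if self.delta_omega == 0:
            return math.pi / 2.0
        return math.atan(self.omega1 / abs(self.delta_omega))


def integrate_ellipse(
    grid: PeakGrid,
    center: tuple[float, float],
    semi_axes: tuple[float, float] = (8.0, 4.0),
) -> float:
    """Sum grid values inside an ellipse around `center` (Hz in both axes).

    The default 8 x 4 Hz semi-axes integrate essentially the crest of an
    amide cross-peak in the 1H and 15N dimensions respectively.
    """
    ch, cn = center
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    h_lo, h_hi = min(grid.h_axis[0], grid.h_axis[-1]), max(grid.h_axis[0], grid.h_axis[-1])
    n_lo, n_hi = min(grid.n_axis[0], grid.n_axis[-1]), max(grid.n_axis[0], grid.n_axis[-1])
    if not (h_lo <= ch - a and ch + a <= h_hi and n_lo <= cn - b and cn + b <= n_hi):
        raise ValueError("integration ellipse extends beyond the grid")
    dh = (grid.h_axis - ch) / a
    dn = (grid.n_axis - cn) / b
    mask = dh[:, None] ** 2 + dn[None, :] ** 2 <= 1.0
    return float(grid.values[mask].sum())


# -- exponential fitting ----------------------------------------------


def _sse_profile(rate: np.ndarray | float, t: np.ndarray, v: np.ndarray):
    """SSE of I0*exp(-R t) with I0 profiled out; also returns optimal I0."""
    e = np.exp(-np.multiply.outer(rate, t))
    sve = e @ v if e.ndim > 1 else float(np.dot(e, v))
    see = np.sum(e * e, axis=-1)
    i0 = sve / see
    sse = np.sum(v * v) - sve * i0
    return sse, i0


def _fit_single(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Best (rate, amplitude) for one decay by 1-D profiled least squares."""
    pos = v > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(v[pos]), 1)[0]
        r0 = -float(slope)
    else:
        r0 = 1.0 / float(np.mean(t))
    span = max(abs(r0), 1.0 / float(np.max(t)))
    res = optimize.minimize_scalar(
        lambda r: _sse_profile(r, t, v)[0],
        bounds=(r0 - 50.0 * span, r0 + 50.0 * span),
        method="bounded",
        options={"xatol": 1e-12},
    )
    rate = float(res.x)
    _, i0 = _sse_profile(rate, t, v)
    return rate, float(i0)


def _fit_many(t: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Vectorized decay-rate fits for replicate matrix V (n_rep, n_points).

    Profiled 1-D least squares in the rate; damped Newton from the
    log-linear start, with a scalar-solver fallback for stragglers.
    """
    W = np.clip(V, 1e-12, None)
    # weighted log-linear start (weights ~ V to de-emphasize noisy tail)
    logv = np.log(W)
    w = W
    sw = w.sum(axis=1)
    swt = w @ t
    swt2 = w @ (t * t)
    swy = np.sum(w * logv, axis=1)
    swty = np.sum(w * t[None, :] * logv, axis=1)
    denom = sw * swt2 - swt**2
    slope = (sw * swty - swt * swy) / np.where(denom == 0, 1.0, denom)
    R = -slope

    def grad(Rv: np.ndarray) -> np.ndarray:
        e = np.exp(-np.multiply.outer(Rv, t))
        sve = np.sum(e * V, axis=1)
        see = np.sum(e * e, axis=1)
        dsve = -np.sum(e * V * t[None, :], axis=1)
        dsee = -2.0 * np.sum(e * e * t[None, :], axis=1)
        # d/dR of (-sve^2/see)
        return -(2.0 * sve * dsve * see - sve**2 * dsee) / see**2

    h = 1e-7 * np.maximum(np.abs(R), 1.0)
    for _ in range(60):
        g = grad(R)
        gp = (grad(R + h) - grad(R - h)) / (2.0 * h)
        step = np.where(gp > 0, g / np.where(gp == 0, 1.0, gp), np.sign(g) * 0.1)
        step = np.clip(step, -5.0, 5.0)
        R = R - step
        if np.max(np.abs(step)) < 1e-12:
            break
    bad = np.abs(grad(R)) > 1e-6 * np.maximum(1.0, np.sum(V * V, axis=1))
    for i in np.nonzero(bad)[0]:
        R[i] = _fit_single(t, V[i])[0]
    return R


class ExponentialRateFitter(BaseEstimator):
    """Two-parameter single-exponential decay fit with Monte-Carlo errors.

    Fits I(t) = I0 exp(-R t) by least squares; the rate error is the
    standard deviation of rates refitted on `n_mc` synthetic series
    resampled from the fitted curve with Gaussian noise of the series'
    sigma (parametric bootstrap).  Replicates that draw a non-positive
    volume are redrawn (and logged) so every replicate is a physical
    decay.

    Attributes (after fit): rate_, rate_error_, amplitude_, n_mc_,
    negative_rate_.
    """

    def __init__(self, n_mc: int = 500, seed: int | None = None):
        self.n_mc = n_mc
        self.seed = seed

    def fit(self, delays, volumes, sigma: float | None = None) -> "ExponentialRateFitter":
        t = np.asarray(delays, dtype=float)
        v = np.asarray(volumes, dtype=float)
        if t.size != v.size or t.size < 3:
            raise ValueError("need matching delays/volumes with >= 3 points")
        if np.unique(t).size < 2:
            raise ValueError("all delays identical; rate is not identifiable")
        rate, i0 = _fit_single(t, v)
        resid = v - i0 * np.exp(-rate * t)
        if sigma is None or sigma == 0:
            # rms residual as the noise estimate when none is supplied
            est = float(np.sqrt(np.mean(resid**2)))
            sigma_eff = est
        else:
            sigma_eff = float(sigma)

        if sigma_eff > 0 and self.n_mc > 0:
            rng = np.random.default_rng(self.seed)
            model_curve = i0 * np.exp(-rate * t)
            reps = np.empty((self.n_mc, t.size))
            n_redrawn = 0
            filled = 0
            while filled < self.n_mc:
                draw = model_curve[None, :] + rng.normal(
                    0.0, sigma_eff, size=(self.n_mc - filled, t.size)
                )
                ok = np.all(draw > 0, axis=1)
                n_bad = int((~ok).sum())
                if n_bad:
                    n_redrawn += n_bad
                    if n_redrawn > 100 * self.n_mc:
                        raise RuntimeError(
                            "Monte-Carlo replicates persistently non-positive; "
                            "noise level inconsistent with decay amplitude"
                        )
                good = draw[ok]
                reps[filled : filled + good.shape[0]] = good
                filled += good.shape[0]
            if n_redrawn:
                logger.info("redrew %d Monte-Carlo replicates with non-positive volumes",
                            n_redrawn)
            mc_rates = _fit_many(t, reps)
            rate_error = float(np.std(mc_rates, ddof=1))
        else:
            rate_error = 0.0

        self.rate_ = float(rate)
        self.rate_error_ = rate_error
        self.amplitude_ = float(i0)
        self.sigma_ = sigma_eff
        self.n_mc_ = int(self.n_mc if sigma_eff > 0 else 0)
        self.negative_rate_ = bool(rate < 0)
        if self.negative_rate_:
            logger.warning("fitted rate is negative (%.3g 1/s); flagged, not clamped", rate)
        return self


def fit_exponential(series: DecaySeries, n_mc: int = 500, seed: int | None = None) -> RateEstimate:
    """Fit one decay series; thin wrapper over ExponentialRateFitter."""
    est = ExponentialRateFitter(n_mc=n_mc, seed=seed).fit(
        series.delays, series.volumes, sigma=series.sigma or None
    )
    return RateEstimate(
        rate=est.rate_,
        rate_error=est.rate_error_,
        amplitude=est.amplitude_,
        n_mc=est.n_mc_,
        negative_rate=est.negative_rate_,
    )


def r2_from_r1rho(r1rho: float, r1: float, geom: SpinLockGeometry) -> float:
    """Effective transverse rate from a rotating-frame rate.

    Solves R1rho = R1 cos^2(theta) + R2eff sin^2(theta) for R2eff; the
    result still folds in any exchange contribution.
    """
    theta = geom.theta
    s2t, c2t = math.sin(theta) ** 2, math.cos(theta) ** 2
    if s2t == 0:
        raise ValueError("tilt angle has sin(theta) = 0; R2 not recoverable")
    if r1rho < r1 * c2t:
        raise ValueError(
            f"R1rho={r1rho} below R1*cos^2(theta)={r1 * c2t:.4g}: inconsistent "
            "rates (noise or mis-assignment)"
        )
    return (r1rho - r1 * c2t) / s2t


def hetero_noe(
    saturated: float, unsaturated: float, sigmas: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Steady-state 15N-{1H} NOE as the saturated/unsaturated intensity ratio.

    Returns (noe, noe_error) with the error from first-order propagation
    of the two intensity uncertainties.
    """
    if unsaturated <= 0:
        raise ValueError("unsaturated intensity must be positive")
    s_sat, s_un = sigmas
    if s_sat < 0 or s_un < 0:
        raise ValueError("intensity uncertainties must be non-negative")
    noe = saturated / unsaturated
    err = math.hypot(s_sat / unsaturated, saturated * s_un / unsaturated**2)
    return noe, err
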