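"""Exact identification of (V0, alpha, beta) from three increasing volumes.

Three dated measurements (t0,V0), (t1,V1), (t2,V2) with V0 < V1 < V2
determine the three Von Bertalanffy parameters exactly: V0 is pinned to the
first measurement and the remaining two parameters follow from requiring the
closed-form trajectory to interpolate V1 and V2.  Eliminating alpha leaves a
one-dimensional root problem in the growth exponent beta,

    g(beta) = [V2^(1-beta) - V1^(1-beta)] / [V1^(1-beta) - V0^(1-beta)]
            = (t2 - t1) / (t1 - t0) =: r,

with the log-ratio limit g(1) = log(V2/V1) / log(V1/V0).  g is positive and
strictly decreasing from +inf (beta -> -inf) to 0 (beta -> +inf), so the
root exists and is unique for every admissible triplet; it is found by
bracketed Brent iteration on log g(beta) - log r (same root, far better
conditioned at the extremes of the bracket).  alpha is then back-substituted:

    alpha = [V1^(1-beta) - V0^(1-beta)] / [(1-beta) * (t1 - t0)],

or alpha = log(V1/V0)/(t1-t0) at beta = 1.

This module also provides the two-point instantaneous growth rates

    lambda = log(V_b / V_a) / (t_b - t_a)   [1/month, natural log],

computed once over the first scan pair (lambda1) and once over the second
(lambda2).  Fitted beta > 1 is equivalent to lambda2 > lambda1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy.optimize import brentq

from .growth import BETA_ONE_BAND, VBParameters, blowup_time, vb_volume

__all__ = [
    "LesionSeries",
    "FitResult",
    "GrowthRates",
    "InclusionError",
    "fit_vb_exponent",
    "growth_rate",
    "growth_rates",
    "DEFAULT_BRACKET",
    "MAX_BRACKET",
]

DEFAULT_BRACKET = (-5.0, 10.0)
MAX_BRACKET = (-50.0, 100.0)

_LABELS = ("PD", "RN", "unknown")
_SUBGROUPS = ("SRS", "FSRT")


class InclusionError(ValueError):
    """Series fails the inclusion criterion of three increasing volumes."""


@dataclass(frozen=True)
class LesionSeries:
    """One lesion's dated volume measurements.

    ``times`` are months (strictly increasing), ``volumes`` cm^3 (positive);
    both the same length, at least two points.  ``label`` is the outcome
    class ("PD" progressive disease, "RN" radiation necrosis, or "unknown"),
    ``subgroup`` the focal radiation modality ("SRS" single-session
    radiosurgery or "FSRT" fractionated radiotherapy), and ``upfront_wbrt``
    whether whole-brain radiotherapy preceded the focal treatment.
    """

    lesion_id: str
    patient_id: str
    times: tuple
    volumes: tuple
    label: str = "unknown"
    subgroup: str | None = None
    upfront_wbrt: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "volumes", tuple(float(v) for v in self.volumes))
        if len(self.times) != len(self.volumes):
            raise ValueError("times and volumes must have equal length")
        if len(self.times) < 2:
            raise ValueError("a series needs at least two measurements")
        for t in self.times:
            if not math.isfinite(t):
                raise ValueError(f"non-finite time {t!r}")
        for v in self.volumes:
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"volumes must be positive and finite, got {v!r}")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")
        if self.subgroup is not None and self.subgroup not in _SUBGROUPS:
            raise ValueError(
                f"subgroup must be one of {_SUBGROUPS} or None, got {self.subgroup!r}"
            )

    @property
    def eligible(self) -> bool:
        """True if the first three volumes increase strictly (the study's
        inclusion criterion for exponent identification)."""
        return (
            len(self.volumes) >= 3
            and self.volumes[0] < self.volumes[1] < self.volumes[2]
        )


@dataclass(frozen=True)
class GrowthRates:
    """Two-point instantaneous growth rates, 1/month."""

    lambda1: float
    lambda2: float


@dataclass(frozen=True)
class FitResult:
    """Outcome of the three-point exponent identification.

    ``ratio_residual`` is |g(beta) - r| at the solution; ``bracket`` the
    (possibly expanded) beta interval actually used; ``status`` is
    "converged" or "failed".  When converged, the trajectory defined by
    ``params`` reproduces all three volumes to <= 1e-6 relative error and
    any blow-up lies beyond the third scan.
    """

    params: VBParameters | None
    ratio_residual: float
    bracket: tuple
    iterations: int
    status: str
    message: str = ""

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def _log_expm1(x: float) -> float:
    """log(expm1(x)) for x > 0, safe against overflow."""
    if x > 36.0:  # expm1(x) == exp(x) to double precision
        return x + math.log1p(-math.exp(-x))
    return math.log(math.expm1(x))


def _log_g(beta: float, log_ratio_1: float, log_ratio_2: float) -> float:
    """log of the interpolation function g(beta).

    ``log_ratio_1 = log(V1/V0)``, ``log_ratio_2 = log(V2/V1)``; both are
    positive for an eligible series, which makes g positive for every beta.
    """
    u = 1.0 - beta
    if abs(u) < BETA_ONE_BAND:
        return math.log(log_ratio_2 / log_ratio_1)
    if u > 0:
        return u * log_ratio_1 + _log_expm1(u * log_ratio_2) - _log_expm1(u * log_ratio_1)
    # u < 0: expm1(u*L) lies in (-1, 0); the two signs cancel.
    return (
        u * log_ratio_1
        + math.log(-math.expm1(u * log_ratio_2))
        - math.log(-math.expm1(u * log_ratio_1))
    )


def fit_vb_exponent(
    series: LesionSeries,
    beta_bracket: tuple = DEFAULT_BRACKET,
    tol: float = 1e-10,
) -> FitResult:
    """Identify (V0, alpha, beta) exactly from the first three measurements.

    Parameters
    ----------
    series:
        Lesion series whose first three points must have strictly increasing
        volumes (:class:`InclusionError` otherwise).  Points beyond the third
        are ignored by the fit.
    beta_bracket:
        Initial root bracket for beta; doubled outward up to (-50, 100) if
        the root is not sign-bracketed.
    tol:
        Absolute tolerance on beta for the Brent solve.

    Returns
    -------
    FitResult
        With ``status="converged"`` the fitted trajectory passes through all
        three volumes to <= 1e-6 relative error; ``status="failed"`` carries
        a diagnostic message instead of parameters.
    """
    if len(series.times) < 3:
        raise ValueError("exponent identification needs at least three points")
    if not series.eligible:
        raise InclusionError(
            f"lesion {series.lesion_id}: volumes must increase at each of the "
            f"first three time points (got {series.volumes[:3]})"
        )
    t0, t1, t2 = series.times[:3]
    v0, v1, v2 = series.volumes[:3]
    dt1, dt2 = t1 - t0, t2 - t1
    log_r1 = math.log(v1 / v0)
    log_r2 = math.log(v2 / v1)
    r = dt2 / dt1
    log_r = math.log(r)

    def h(beta: float) -> float:
        return _log_g(beta, log_r1, log_r2) - log_r

    lo, hi = float(beta_bracket[0]), float(beta_bracket[1])
    if not lo < hi:
        raise ValueError(f"invalid beta bracket {beta_bracket}")
    # g is decreasing, so require h(lo) > 0 > h(hi); expand outward by
    # doubling until sign change or the hard cap is hit.
    while h(lo) * h(hi) > 0:
        if (lo, hi) == MAX_BRACKET:
            return FitResult(
                params=None,
                ratio_residual=math.nan,
                bracket=(lo, hi),
                iterations=0,
                status="failed",
                message=(
                    f"lesion {series.lesion_id}: no sign change of g(beta)-r in "
                    f"beta bracket ({lo}, {hi}); series is degenerate for this model"
                ),
            )
        lo = max(2.0 * lo, MAX_BRACKET[0])
        hi = min(2.0 * hi, MAX_BRACKET[1])
    beta, info = brentq(h, lo, hi, xtol=tol, full_output=True)
    if abs(beta - 1.0) < BETA_ONE_BAND:
        beta = 1.0
        alpha = log_r1 / dt1
    else:
        u = 1.0 - beta
        alpha = v0**u * math.expm1(u * log_r1) / (u * dt1)
    params = VBParameters(v0=v0, alpha=alpha, beta=beta, t0=t0)
    residual = abs(math.exp(_log_g(beta, log_r1, log_r2)) - r)

    # Converged only if the trajectory actually reproduces the data and the
    # blow-up (if any) lies beyond the last fitted scan.
    status, message = "converged", ""
    if blowup_time(params) <= t2:
        status, message = "failed", "blow-up before the third scan"
    else:
        for t_obs, v_obs in ((t1, v1), (t2, v2)):
            if abs(vb_volume(params, t_obs) - v_obs) > 1e-6 * v_obs:
                status, message = "failed", "trajectory does not reproduce the data"
                break
    return FitResult(
        params=params if status == "converged" else None,
        ratio_residual=residual,
        bracket=(lo, hi),
        iterations=int(info.iterations),
        status=status,
        message=message,
    )


def growth_rate(v_a: float, v_b: float, t_a: float, t_b: float) -> float:
    """Instantaneous growth rate log(V_b/V_a)/(t_b - t_a), 1/month.

    Natural logarithm; positive when the volume grows.
    """
    if t_b <= t_a:
        raise ValueError(f"t_b={t_b} must exceed t_a={t_a}")
    if v_a <= 0 or v_b <= 0:
        raise ValueError("volumes must be positive")
    return math.log(v_b / v_a) / (t_b - t_a)


def growth_rates(series: LesionSeries) -> GrowthRates:
    """lambda1 from the first scan pair, lambda2 from the second."""
    if len(series.times) < 3:
        raise ValueError("growth rates need at least three points")
    t0, t1, t2 = series.times[:3]
    v0, v1, v2 = series.volumes[:3]
    return GrowthRates(
        lambda1=growth_rate(v0, v1, t0, t1),
        lambda2=growth_rate(v1, v2, t1, t2),
    )
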