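"""Von Bertalanffy power-law growth model.

Lesion volume is assumed to follow the ordinary differential equation

    dV/dt = alpha * V**beta,    V(t0) = V0,

with volume in cm^3 and time in months.  ``beta`` is the dimensionless
growth exponent: ``beta < 1`` gives decelerating (sub-exponential) growth,
``beta = 1`` exponential growth, and ``beta > 1`` super-exponential growth
that diverges in finite time (the "blow-up").  The closed-form solution for
``beta != 1`` is

    V(t) = [V0**(1-beta) + alpha*(1-beta)*(t - t0)]**(1/(1-beta)),

and for ``beta = 1`` the exponential limit ``V(t) = V0*exp(alpha*(t-t0))``.
The exponential branch is also used inside a narrow band around ``beta = 1``
to avoid catastrophic cancellation in ``1 - beta``.

Only growing lesions (``alpha > 0``) are modelled; series that shrink are
rejected upstream by the fitting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BETA_ONE_BAND",
    "BlowupError",
    "VBParameters",
    "blowup_time",
    "vb_volume",
    "vb_trajectory",
]

#: Half-width of the band around beta = 1 inside which the analytic
#: exponential limit is used instead of the power-law closed form.
BETA_ONE_BAND = 1e-7


class BlowupError(ValueError):
    """Raised when a trajectory is evaluated at or beyond its blow-up time."""


@dataclass(frozen=True)
class VBParameters:
    """Parameters of the Von Bertalanffy law ``dV/dt = alpha * V**beta``.

    Attributes
    ----------
    v0:
        Volume in cm^3 at the reference time ``t0``; must be positive.
    alpha:
        Growth coefficient in cm^3^(1-beta) / month; must be positive
        (only growing lesions are modelled).
    beta:
        Dimensionless growth exponent.  Any finite value is accepted;
        values far outside [-5, 10] are usually a fitting diagnostic
        rather than biology.
    t0:
        Reference time in months.  Stored as given; the fitting layer
        normalises it to the first scan of a series.
    """

    v0: float
    alpha: float
    beta: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v0", "alpha", "beta", "t0"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ValueError(f"{name} must be a finite number, got {value!r}")
        if self.v0 <= 0:
            raise ValueError(f"v0 must be positive, got {self.v0}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


def blowup_time(params: VBParameters) -> float:
    """Finite-time divergence of the trajectory, or ``+inf`` if none.

    For ``beta > 1`` the closed form diverges at

        t* = t0 + V0**(1-beta) / (alpha * (beta - 1));

    for ``beta <= 1`` the solution exists for all time and ``+inf`` is
    returned.  ``beta`` within :data:`BETA_ONE_BAND` of 1 is treated as
    exactly exponential.
    """
    if params.beta <= 1.0 + BETA_ONE_BAND:
        return math.inf
    u = 1.0 - params.beta  # negative here
    return params.t0 + params.v0**u / (params.alpha * (params.beta - 1.0))


def vb_volume(params: VBParameters, t: float) -> float:
    """Closed-form volume at time ``t`` (months), in cm^3.

    ``t`` must be at or after the reference time and, for super-exponential
    exponents, strictly before :func:`blowup_time`.
    """
    if not isinstance(t, (int, float)) or not math.isfinite(t):
        raise ValueError(f"t must be a finite number, got {t!r}")
    if t < params.t0:
        raise ValueError(f"t={t} precedes the reference time t0={params.t0}")
    dt = t - params.t0
    if abs(params.beta - 1.0) < BETA_ONE_BAND:
        return params.v0 * math.exp(params.alpha * dt)
    u = 1.0 - params.beta
    inner = params.v0**u + params.alpha * u * dt
    if inner <= 0.0:
        raise BlowupError(
            f"volume diverges at the blow-up time t = {blowup_time(params):.6g} "
            f"months; cannot evaluate at t = {t:.6g}"
        )
    return inner ** (1.0 / u)


def vb_trajectory(params: VBParameters, times: Sequence[float]) -> np.ndarray:
    """Element-wise :func:`vb_volume` over an ascending time grid.

    Returns a float array of volumes; output is strictly increasing because
    ``alpha > 0``.
    """
    ts = np.asarray(times, dtype=float)
    if ts.ndim != 1 or ts.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(ts) < 0):
        raise ValueError("times must be sorted ascending")
    return np.array([vb_volume(params, float(t)) for t in ts])
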