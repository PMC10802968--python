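"""Calibration of the exponential censoring rate.

Simulation scenarios fix the expected censoring fraction ``p`` by drawing
censoring times C ~ Exp(theta) independently of the lifetimes T (missing at
random).  A record is censored when C < T, so

    p(theta) = E_x[ integral_0^inf theta * exp(-theta*c) * S_T(c | x) dc ],

mixing over the binary covariate that drives the scale regression
``scale = exp(b1 + b2*x)``.  ``p(theta)`` is continuous and strictly
increasing in theta, so the target fraction is matched by a bracketing root
search.  ``theta`` is a *rate*: the censoring law has mean ``1/theta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .distributions import BSParams, Params, WeibullParams

__all__ = ["CensoringSpec", "EventModelMixture", "expected_censoring_fraction", "calibrate_theta"]


@dataclass(frozen=True)
class CensoringSpec:
    """An exponential censoring rate paired with its nominal fraction."""

    theta: float
    target_p: float

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0 < self.target_p < 1:
            raise ValueError("target_p must lie in (0, 1)")


@dataclass(frozen=True)
class EventModelMixture:
    """Lifetime model with covariate-linked scale, mixed over x ~ Bernoulli.

    ``family`` is 'weibull' (coefficients parameterise the PH rate
    ``beta = exp(b1 + b2*x)``) or 'bs' (coefficients parameterise the scale
    ``delta = exp(b1 + b2*x)``).
    """

    family: str
    shape: float
    b1: float
    b2: float
    covariate_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("weibull", "bs"):
            raise ValueError("family must be 'weibull' or 'bs'")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if not 0 <= self.covariate_prob <= 1:
            raise ValueError("covariate_prob must lie in [0, 1]")

    def component(self, x: int) -> Params:
        scale = float(np.exp(self.b1 + self.b2 * x))
        if self.family == "weibull":
            return WeibullParams(self.shape, scale)
        return BSParams(self.shape, scale)

    def components(self) -> list[tuple[float, Params]]:
        """(weight, lifetime model) pairs for x = 0, 1."""
        p1 = self.covariate_prob
        out = []
        if p1 < 1:
            out.append((1.0 - p1, self.component(0)))
        if p1 > 0:
            out.append((p1, self.component(1)))
        return out


def expected_censoring_fraction(theta: float, model: EventModelMixture) -> float:
    """P(C < T) for C ~ Exp(theta) independent of T.

    Both-exponential components (Weibull shape 1) use the competing-risks
    closed form theta/(theta + beta); the rest are integrated numerically.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    total = 0.0
    for weight, comp in model.components():
        if isinstance(comp, WeibullParams) and comp.shape_alpha == 1.0:
            total += weight * theta / (theta + comp.rate_beta)
            continue
        # substitute v = theta*c so the integrand has unit scale for any rate
        val, err = integrate.quad(
            lambda v: np.exp(-v) * float(comp.sf(v / theta)),
            0.0,
            np.inf,
            limit=500,
            epsabs=1e-12,
            epsrel=1e-11,
        )
        if not np.isfinite(val) or err > 1e-8:
            raise FloatingPointError(
                f"censoring-fraction quadrature failed (value={val}, err={err})"
            )
        total += weight * val
    return float(min(max(total, 0.0), 1.0))


def calibrate_theta(
    target_p: float, model: EventModelMixture, tol: float = 1e-10
) -> float:
    """Rate theta* with expected censoring fraction equal to ``target_p``.

    Brackets the root by doubling/halving around an initial guess, then
    solves with Brent's method to ``|p(theta*) - target_p| < 1e-8``.
    """
    if not 0 < target_p < 1:
        raise ValueError("target_p must lie in (0, 1)")

    def g(theta: float) -> float:
        return expected_censoring_fraction(theta, model) - target_p

    lo, hi = 1e-3, 1.0
    for _ in range(60):
        if g(lo) < 0:
            break
        lo /= 2.0
    else:
        raise FloatingPointError("failed to bracket theta from below")
    for _ in range(60):
        if g(hi) > 0:
            break
        hi *= 2.0
    else:
        raise FloatingPointError("failed to bracket theta from above")
    theta = optimize.brentq(g, lo, hi, xtol=tol, rtol=8.9e-16)
    return float(theta)
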