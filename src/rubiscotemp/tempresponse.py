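"""Temperature-response fitting: Arrhenius, polynomials, Q10.

Each species x trait temperature series is fitted with an Arrhenius-type
function f(T) = exp(c - dHa / (R T)) by minimizing the sum of squared
residuals on the raw value scale (the log-linear closed form serves as the
initializer and as an independent cross-check on noiseless data), and
optionally with second/third-order polynomials in degC.  Fits are evaluated
at the five standard temperatures 5/15/25/35/45 degC, from which the four
Q10 values over consecutive 10-degree intervals follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .physchem import R

__all__ = [
    "STANDARD_TEMPS_C",
    "Q10_INTERVALS",
    "ArrheniusFit",
    "PolynomialFit",
    "StandardizedResponse",
    "arrhenius_value",
    "fit_arrhenius",
    "loglinear_arrhenius",
    "fit_polynomial",
    "q10",
    "standard_response",
    "fit_quality",
]

#: Standard reporting temperatures, degC.
STANDARD_TEMPS_C = (5.0, 15.0, 25.0, 35.0, 45.0)
#: Q10 interval lower bounds, degC.
Q10_INTERVALS = ((5.0, 15.0), (15.0, 25.0), (25.0, 35.0), (35.0, 45.0))


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters for one species x trait.

    ``c`` is the dimensionless scaling constant, ``dha`` the activation
    energy in J mol-1 (negative for traits that decline with warming), ``r``
    the Pearson correlation of predicted vs measured (None when only two
    temperatures were assayed).
    """

    c: float
    dha: float
    r: Optional[float]
    n_points: int
    t_range: tuple[float, float]

    def value(self, temperature: float):
        return arrhenius_value(self.c, self.dha, temperature)


@dataclass(frozen=True)
class PolynomialFit:
    """Ordinary least-squares polynomial in degC (order 2 or 3).

    ``coefficients`` are ascending powers (a, b, c[, d])."""

    order: int
    coefficients: tuple[float, ...]
    r: Optional[float]
    n_points: int
    t_range: tuple[float, float]

    def value(self, temperature: float):
        tc = np.asarray(temperature, dtype=float) - 273.15
        return sum(coef * tc**k for k, coef in enumerate(self.coefficients))


@dataclass(frozen=True)
class StandardizedResponse:
    """Trait values at the five standard temperatures and the four Q10s.

    ``extrapolated`` flags which standard temperatures fall outside the
    fitted range (polynomial fits in particular are unreliable there)."""

    values: tuple[float, ...]
    q10: tuple[float, ...]
    extrapolated: tuple[bool, ...]


def arrhenius_value(c: float, dha: float, temperature):
    """Evaluate exp(c - dHa / (R T)); ``dha`` in J mol-1, ``temperature`` in K."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("absolute temperature must be positive")
    out = np.exp(c - dha / (R * t))
    return float(out) if np.isscalar(temperature) else out


def loglinear_arrhenius(temps_k: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """Closed-form log-linear regression ln v = c - dHa/(R T); returns (c, dHa).

    Exact for noiseless Arrhenius data; used to initialize (and, in tests,
    cross-check) the raw-scale fit.
    """
    t = np.asarray(temps_k, dtype=float)
    v = np.asarray(values, dtype=float)
    slope, intercept = np.polyfit(1.0 / t, np.log(v), 1)
    return float(intercept), float(-slope * R)


def fit_arrhenius(temps_k: Sequence[float], values: Sequence[float]) -> ArrheniusFit:
    """Fit the Arrhenius function by raw-scale least squares.

    Requires >= 2 points at distinct temperatures with positive values.  With
    exactly two points the exact interpolant is returned and ``r`` is None
    ("not determined"); with three or more, the log-linear closed form seeds
    a Levenberg-Marquardt-style refinement of the raw-scale sum of squares.
    """
    t = np.asarray(temps_k, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValueError("temperatures and values must have equal length")
    if t.size < 2:
        raise ValueError("at least two points are required")
    if np.unique(t).size != t.size:
        raise ValueError("temperatures must be distinct")
    if np.any(v <= 0):
        raise ValueError("values must be positive")

    if t.size == 2:
        # exact two-point interpolant
        dha = R * math.log(v[1] / v[0]) / (1.0 / t[0] - 1.0 / t[1])
        c = math.log(v[0]) + dha / (R * t[0])
        return ArrheniusFit(c, dha, None, 2, (float(t.min()), float(t.max())))

    c0, dha0 = loglinear_arrhenius(t, v)
    scale = float(np.mean(v))  # residuals on a O(1) scale for the optimizer

    def residuals(p):
        return (np.exp(p[0] - p[1] / (R * t)) - v) / scale

    sol = optimize.least_squares(residuals, x0=[c0, dha0], method="lm",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    c, dha = float(sol.x[0]), float(sol.x[1])
    predicted = arrhenius_value(c, dha, t)
    r = fit_quality(predicted, v)
    return ArrheniusFit(c, dha, r, int(t.size), (float(t.min()), float(t.max())))


def fit_polynomial(temps_k: Sequence[float], values: Sequence[float],
                   order: int = 2) -> PolynomialFit:
    """Ordinary least squares polynomial of ``order`` 2 or 3, with degC as the
    regressor.  Exact interpolation when n equals order + 1."""
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    t = np.asarray(temps_k, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < order + 1:
        raise ValueError(f"order-{order} fit requires at least {order + 1} points")
    tc = t - 273.15
    coeffs = np.polyfit(tc, v, order)[::-1]  # ascending powers
    predicted = sum(c * tc**k for k, c in enumerate(coeffs))
    r = fit_quality(predicted, v)
    return PolynomialFit(order, tuple(float(c) for c in coeffs), r,
                         int(t.size), (float(t.min()), float(t.max())))


def q10(dha: float, t_low: float) -> float:
    """Closed-form Q10 of an Arrhenius process over [t_low, t_low + 10] K:
    exp[(dHa/R)(1/T - 1/(T+10))]; identical to the value ratio
    f(T+10)/f(T)."""
    if t_low <= 0:
        raise ValueError("absolute temperature must be positive")
    return math.exp((dha / R) * (1.0 / t_low - 1.0 / (t_low + 10.0)))


def standard_response(fit: ArrheniusFit | PolynomialFit) -> StandardizedResponse:
    """Evaluate a fit at the five standard temperatures and derive the four
    interval Q10s.  Standard temperatures outside the fitted range are
    flagged as extrapolated, not refused."""
    temps_k = tuple(tc + 273.15 for tc in STANDARD_TEMPS_C)
    values = tuple(float(fit.value(t)) for t in temps_k)
    q10s = tuple(values[i + 1] / values[i] for i in range(4))
    lo, hi = fit.t_range
    extrapolated = tuple(not (lo <= t <= hi) for t in temps_k)
    return StandardizedResponse(values, q10s, extrapolated)


def fit_quality(predicted: Sequence[float], measured: Sequence[float]) -> Optional[float]:
    """Pearson correlation of predicted vs measured values; None ("not
    determined") for fewer than three points."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.size != m.size:
        raise ValueError("predicted and measured must have equal length")
    if p.size < 3:
        return None
    if np.allclose(p, p[0]) or np.allclose(m, m[0]):
        return None  # correlation undefined at zero variance
    return float(stats.pearsonr(p, m).statistic)
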