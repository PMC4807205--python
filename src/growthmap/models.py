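"""Candidate growth laws and their qualitative dynamics.

Four growth mechanisms are considered for an accumulating level variable:

* constant growth (a linear trend in the level),
* Malthusian growth (``dy/dt = a y``, exponential in time),
* restrained (Verhulst) growth, ``dy/dt = a y - b y^2``, whose carrying
  capacity ``a/b`` is the maximum level the environment sustains, and
* a cubic extension ``x_{t+1} = k1 x - k2 x^2 + k3 x^3`` that allows a
  restrained process to keep creeping upward instead of saturating.

The discrete restrained model, after normalizing the level by its carrying
capacity so the state lives in (0, 1), is the logistic map
``x_{t+1} = k x (1 - x)`` with growth factor ``k = 1 + a``.  Its long-run
behavior is governed entirely by ``k``: decay to zero, convergence to the
fixed point ``(k - 1)/k``, periodic cycling, or deterministic chaos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DivergentOrbit",
    "MapParameters",
    "ContinuousLogisticParams",
    "RegimeLabel",
    "logistic_step",
    "cubic_step",
    "iterate_map",
    "equilibria",
    "classify_regime",
    "continuous_logistic_solution",
    "exponential_solution",
    "growth_base",
]

LOGISTIC = "logistic"
CUBIC = "cubic"

#: default blow-up guards per family: a valid logistic orbit cannot leave
#: [0, 1], while admissible-looking cubic coefficients can still launch the
#: state to infinity and must be caught, not crashed on.
DEFAULT_BLOWUP_BOUND = {LOGISTIC: 1.0, CUBIC: 10.0}


class DivergentOrbit(RuntimeError):
    """Raised when an orbit leaves the admissible region.

    Attributes
    ----------
    step : int
        Index of the first divergent state.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"orbit diverged at step {step}")


@dataclass(frozen=True)
class MapParameters:
    """Parameters of a one-dimensional growth map.

    ``family`` is ``"logistic"`` (single growth factor ``k``) or ``"cubic"``
    (signed coefficients ``(k1, k2, k3)`` of
    ``x_{t+1} = k1 x - k2 x^2 + k3 x^3``; note ``k2`` is stored positive and
    enters with the minus sign).  ``x0`` is the initial condition and
    ``n_steps`` the orbit length (number of states returned, including
    ``x0``).
    """

    family: str
    x0: float
    n_steps: int
    k: float | None = None
    poly_coeffs: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in (LOGISTIC, CUBIC):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not np.isfinite(self.x0):
            raise ValueError("x0 must be finite")
        if self.family == LOGISTIC:
            if self.k is None:
                raise ValueError("logistic family requires k")
            if not (0.0 <= self.k <= 4.0):
                raise ValueError(f"k={self.k} outside [0, 4]")
            if not (0.0 < self.x0 < 1.0):
                raise ValueError(f"x0={self.x0} outside (0, 1)")
        else:
            if self.poly_coeffs is None or len(self.poly_coeffs) != 3:
                raise ValueError("cubic family requires poly_coeffs=(k1, k2, k3)")

    @property
    def growth_rate(self) -> float:
        """The differential-model growth rate a = k - 1 (or k1 - 1)."""
        if self.family == LOGISTIC:
            return self.k - 1.0
        return self.poly_coeffs[0] - 1.0

    def signed_polynomial(self) -> tuple[float, float, float]:
        """Coefficients of x, x^2, x^3 with their actual signs.

        The recursion stores ``k2`` positive (it always enters negatively);
        reports print both views to avoid sign ambiguity.
        """
        if self.family == LOGISTIC:
            return (self.k, -self.k, 0.0)
        k1, k2, k3 = self.poly_coeffs
        return (k1, -k2, k3)


@dataclass(frozen=True)
class ContinuousLogisticParams:
    """Parameters of dy/dt = a*y - b*y^2 with y(t0) = y0 > 0.

    ``a`` is the intrinsic growth rate per unit time, ``b`` the restraint
    coefficient; the carrying capacity is ``a/b``.
    """

    a: float
    b: float
    y0: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.y0 > 0):
            raise ValueError("require a > 0, b > 0, y0 > 0")

    @property
    def carrying_capacity(self) -> float:
        return self.a / self.b


@dataclass(frozen=True)
class RegimeLabel:
    """Qualitative dynamics class of a logistic growth factor ``k``."""

    regime: str
    equilibria: tuple[float, ...]
    k: float


def logistic_step(k: float, x: float) -> float:
    """One application of x -> k*x*(1-x); arguments are bounds-checked."""
    if not (0.0 <= k <= 4.0):
        raise ValueError(f"k={k} outside [0, 4]")
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"x={x} outside [0, 1]")
    return k * x * (1.0 - x)


def cubic_step(coeffs: tuple[float, float, float], x: float) -> float:
    """One application of x -> k1*x - k2*x^2 + k3*x^3 (k2 stored positive)."""
    k1, k2, k3 = coeffs
    return k1 * x - k2 * x * x + k3 * x * x * x


def iterate_map(params: MapParameters, blowup_bound: float | None = None) -> np.ndarray:
    """Iterate the map; returns the orbit ``[x0, x1, ..., x_{n_steps-1}]``.

    Raises :class:`DivergentOrbit` (carrying the step index) if a state is
    non-finite or its magnitude exceeds the blow-up bound.
    """
    if blowup_bound is None:
        blowup_bound = DEFAULT_BLOWUP_BOUND[params.family]
    orbit = np.empty(params.n_steps)
    x = float(params.x0)
    orbit[0] = x
    if params.family == LOGISTIC:
        k = params.k
        for t in range(1, params.n_steps):
            x = k * x * (1.0 - x)
            if not math.isfinite(x) or abs(x) > blowup_bound:
                raise DivergentOrbit(t)
            orbit[t] = x
    else:
        k1, k2, k3 = params.poly_coeffs
        for t in range(1, params.n_steps):
            x = k1 * x - k2 * x * x + k3 * x * x * x
            if not math.isfinite(x) or abs(x) > blowup_bound:
                raise DivergentOrbit(t)
            orbit[t] = x
    return orbit


def equilibria(k: float) -> tuple[float, ...]:
    """Fixed points of the logistic map at growth factor k.

    For k <= 1 the nontrivial root (k-1)/k is non-positive and inadmissible
    as a population level, so only 0 is returned.
    """
    if not (0.0 <= k <= 4.0):
        raise ValueError(f"k={k} outside [0, 4]")
    if k <= 1.0:
        return (0.0,)
    return (0.0, (k - 1.0) / k)


def classify_regime(k: float) -> RegimeLabel:
    """Qualitative long-run behavior of the logistic map at growth factor k.

    The taxonomy is the coarse applied one: extinction below 1, a stable
    fixed point on [1, 3], the period-doubling band on (3, 3.8), and chaos on
    [3.8, 4].  The band boundaries are the conventional round figures of the
    applied literature, not the exact period-doubling onset 3.5699...; the
    classification is a reading aid for a fitted k, not a bifurcation
    diagram.
    """
    if not np.isfinite(k):
        raise ValueError("k must be finite")
    if k < 0.0 or k > 4.0:
        return RegimeLabel("out_of_range", (), k)
    eq = equilibria(k)
    if k < 1.0:
        regime = "extinction"
    elif k <= 3.0:
        regime = "fixed_point"
    elif k < 3.8:
        regime = "periodic"
    else:
        regime = "chaotic"
    return RegimeLabel(regime, eq, k)


def continuous_logistic_solution(params: ContinuousLogisticParams, t) -> np.ndarray:
    """Closed-form solution of the continuous restrained-growth equation.

    y(t) = a*y0 / (b*y0 + (a - b*y0) * exp(-a*(t - t0)))

    Converges to the carrying capacity a/b as t -> infinity, and is constant
    when started exactly there.
    """
    a, b, y0, t0 = params.a, params.b, params.y0, params.t0
    t = np.asarray(t, dtype=float)
    denom = b * y0 + (a - b * y0) * np.exp(-a * (t - t0))
    if np.any(denom == 0.0):
        raise ZeroDivisionError("degenerate denominator in logistic solution")
    return a * y0 / denom


def exponential_solution(y0: float, a: float, t) -> np.ndarray:
    """Malthusian growth y(t) = y0 * exp(a*t) (= y0 * b**t with b = e**a)."""
    return y0 * np.exp(a * np.asarray(t, dtype=float))


def growth_base(a: float) -> float:
    """The per-step multiplicative base b = e**a of the Malthusian model."""
    return math.exp(a)
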