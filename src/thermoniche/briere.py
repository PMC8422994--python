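"""Modified Briere temperature response model.

The classic Briere curve ``g(T) = c T (T - Tmin) sqrt(Tmax - T)`` is a
unimodal thermal performance curve with fixed skew.  The modified form used
throughout this package,

    g(T) = c (T - Tmin)^a (Tmax - T)^b,        a, b >= 0,  a + b > 0,

frees both shape exponents so left- and right-skewed responses can be fit.
Its optimum has the closed form ``Topt = alpha*Tmax + (1 - alpha)*Tmin`` with
``alpha = a / (a + b)``.  The canonical reparametrization

    g(T) = gmax * [ ((T - Tmin)/alpha)^alpha
                    * ((Tmax - T)/(1 - alpha))^(1 - alpha)
                    / (Tmax - Tmin) ]^s,       s = a + b,

exposes biologically interpretable parameters: peak growth ``gmax``, optimum
location ``alpha`` (fraction of the way from Tmin to Tmax) and steepness
``s``.  Outside ``[Tmin, Tmax]`` growth is defined as exactly 0.

All temperatures are in degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "NaturalBriereParams",
    "CanonicalBriereParams",
    "NicheSummary",
    "briere_original",
    "briere_modified",
    "canonical_evaluate",
    "to_canonical",
    "to_natural",
    "optimal_temperature",
    "half_max_temperatures",
    "niche_summary",
    "ParameterDomainError",
    "DegenerateShapeError",
]


class ParameterDomainError(ValueError):
    """Raised when curve parameters violate their domain constraints."""


class DegenerateShapeError(ParameterDomainError):
    """Raised when a + b = 0, which leaves the curve shapeless."""


@dataclass(frozen=True)
class NaturalBriereParams:
    """Modified Briere parameters in natural (c, Tmin, Tmax, a, b) form.

    ``c`` is a positive scale (growth units per degC^(a+b)); ``a`` and ``b``
    are the dimensionless shape exponents at the cold and hot ends.
    """

    c: float
    t_min: float
    t_max: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.c, self.t_min, self.t_max, self.a, self.b]).all():
            raise ParameterDomainError("parameters must be finite")
        if self.t_min >= self.t_max:
            raise ParameterDomainError(
                f"t_min ({self.t_min}) must be below t_max ({self.t_max})"
            )
        if self.c <= 0:
            raise ParameterDomainError(f"c must be positive, got {self.c}")
        if self.a < 0 or self.b < 0:
            raise ParameterDomainError("shape exponents a, b must be >= 0")
        if self.a + self.b == 0:
            raise DegenerateShapeError("a + b must be positive")


@dataclass(frozen=True)
class CanonicalBriereParams:
    """Modified Briere parameters in canonical (gmax, alpha, s) form.

    ``g_max`` is the peak growth, ``alpha`` in (0, 1) places the optimum
    between ``t_min`` and ``t_max``, and ``s = a + b > 0`` sets how steeply
    the curve rises and falls.
    """

    g_max: float
    alpha: float
    s: float
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        vals = [self.g_max, self.alpha, self.s, self.t_min, self.t_max]
        if not np.isfinite(vals).all():
            raise ParameterDomainError("parameters must be finite")
        if self.t_min >= self.t_max:
            raise ParameterDomainError(
                f"t_min ({self.t_min}) must be below t_max ({self.t_max})"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ParameterDomainError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.s <= 0:
            raise ParameterDomainError(f"s must be positive, got {self.s}")
        if self.g_max <= 0:
            raise ParameterDomainError(f"g_max must be positive, got {self.g_max}")


@dataclass(frozen=True)
class NicheSummary:
    """Optimum and half-maximal thermal niche of a fitted curve.

    ``breadth`` is the width of the interval between the two temperatures at
    which growth equals half its maximum (the thermal niche).
    """

    t_opt: float
    g_max: float
    t_half_low: float
    t_half_high: float
    breadth: float


def briere_original(t, c: float, t_min: float, t_max: float):
    """Classic Briere curve ``c t (t - t_min) sqrt(t_max - t)``, 0 outside.

    The square-root factor is taken as ``sqrt(t_max - t)`` so it is real and
    nonnegative inside the growth range.
    """
    if not t_min < t_max:
        raise ParameterDomainError("t_min must be below t_max")
    if c <= 0:
        raise ParameterDomainError("c must be positive")
    t = np.asarray(t, dtype=float)
    inside = (t >= t_min) & (t <= t_max)
    g = np.zeros_like(t)
    ti = t[inside]
    g[inside] = c * ti * (ti - t_min) * np.sqrt(t_max - ti)
    return g if g.ndim else float(g)


def briere_modified(t, p: NaturalBriereParams):
    """Evaluate ``c (t - t_min)^a (t_max - t)^b``; exactly 0 at and outside the limits."""
    t = np.asarray(t, dtype=float)
    inside = (t > p.t_min) & (t < p.t_max)
    g = np.zeros_like(t)
    ti = t[inside]
    g[inside] = p.c * (ti - p.t_min) ** p.a * (p.t_max - ti) ** p.b
    return g if g.ndim else float(g)


def canonical_evaluate(t, p: CanonicalBriereParams):
    """Evaluate the canonical form; equals ``briere_modified`` after conversion.

    At the optimum the bracketed factor equals 1, so ``g(Topt) = g_max``
    exactly by construction.
    """
    t = np.asarray(t, dtype=float)
    inside = (t > p.t_min) & (t < p.t_max)
    g = np.zeros_like(t)
    ti = t[inside]
    span = p.t_max - p.t_min
    base = (
        ((ti - p.t_min) / p.alpha) ** p.alpha
        * ((p.t_max - ti) / (1.0 - p.alpha)) ** (1.0 - p.alpha)
        / span
    )
    g[inside] = p.g_max * base**p.s
    return g if g.ndim else float(g)


def optimal_temperature(p: NaturalBriereParams | CanonicalBriereParams) -> float:
    """Closed-form optimum ``alpha*t_max + (1 - alpha)*t_min``."""
    if isinstance(p, NaturalBriereParams):
        alpha = p.a / (p.a + p.b)
    else:
        alpha = p.alpha
    return alpha * p.t_max + (1.0 - alpha) * p.t_min


def to_canonical(p: NaturalBriereParams) -> CanonicalBriereParams:
    """Convert natural parameters to the canonical (gmax, alpha, s) form."""
    s = p.a + p.b
    alpha = p.a / s
    if not 0.0 < alpha < 1.0:
        # one-sided shapes (a=0 or b=0) have no interior optimum
        raise ParameterDomainError(
            "canonical form requires a > 0 and b > 0 (interior optimum)"
        )
    t_opt = alpha * p.t_max + (1.0 - alpha) * p.t_min
    g_max = briere_modified(t_opt, p)
    return CanonicalBriereParams(
        g_max=g_max, alpha=alpha, s=s, t_min=p.t_min, t_max=p.t_max
    )


def to_natural(p: CanonicalBriereParams) -> NaturalBriereParams:
    """Invert :func:`to_canonical`; round trip is the identity to ~1e-10 relative."""
    a = p.alpha * p.s
    b = (1.0 - p.alpha) * p.s
    t_opt = optimal_temperature(p)
    c = p.g_max / ((t_opt - p.t_min) ** a * (p.t_max - t_opt) ** b)
    return NaturalBriereParams(c=c, t_min=p.t_min, t_max=p.t_max, a=a, b=b)


def _as_canonical(p) -> CanonicalBriereParams:
    return p if isinstance(p, CanonicalBriereParams) else to_canonical(p)


def half_max_temperatures(
    p: NaturalBriereParams | CanonicalBriereParams, fraction: float = 0.5
) -> tuple[float, float]:
    """Temperatures below and above the optimum where growth equals ``fraction * g_max``.

    Each root is bracketed between the relevant limit and the optimum and
    solved to 1e-6 degC.  ``fraction`` must lie in (0, 1]; at 1 both roots
    collapse onto the optimum.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    cp = _as_canonical(p)
    t_opt = optimal_temperature(cp)
    if fraction == 1.0:
        return (t_opt, t_opt)
    target = fraction * cp.g_max
    eps = 1e-9

    def f(t: float) -> float:
        return canonical_evaluate(t, cp) - target

    # For near-flat curves (tiny s) the crossing can sit within floating-point
    # resolution of a growth limit; the limit itself is then the best answer.
    lo_end = cp.t_min + eps
    lo = lo_end if f(lo_end) >= 0 else bisect(f, lo_end, t_opt, xtol=1e-6)
    hi_end = cp.t_max - eps
    hi = hi_end if f(hi_end) >= 0 else bisect(f, t_opt, hi_end, xtol=1e-6)
    return (float(lo), float(hi))


def niche_summary(p: NaturalBriereParams | CanonicalBriereParams) -> NicheSummary:
    """Aggregate the optimum, peak growth, half-max temperatures and breadth."""
    cp = _as_canonical(p)
    t_opt = optimal_temperature(cp)
    lo, hi = half_max_temperatures(cp, 0.5)
    return NicheSummary(
        t_opt=float(t_opt),
        g_max=float(cp.g_max),
        t_half_low=lo,
        t_half_high=hi,
        breadth=hi - lo,
    )
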