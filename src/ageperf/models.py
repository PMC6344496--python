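"""Closed-form models of the age-performance relationship.

The central object is the integrative model of age performance (IMAP1),
which describes measurable performance across the whole lifespan as the
product of two cell-level processes:

* a saturating growth of the cell population ``N(t)``, driven by a growth
  rate ``alpha(t) = alpha0 * exp(-alphar * t)`` that decays with age
  (replicative senescence), and
* a monotone decline of average cell functionality
  ``beta(t) = beta0 * (1 - exp(betar * (t - td)))`` that reaches zero at an
  explicit time of death ``td``.

Performance is ``P(t) = beta(t) * N(t)``, which in closed form gives the
five-parameter curve implemented by :func:`imap_performance`.  Rescaling
age by the lifespan (``u = t / td``) reduces the curve to a three-shape
family ``x(u)`` (:func:`imap_reduced`) whose parameters are the
dimensionless rates ``alpha0* = alpha0*td``, ``alphar* = alphar*td`` and
``betar* = betar*td``.

Two reference models are provided for comparison: Moore's double
exponential ``P(t) = a(1-e^{-bt}) + c(1-e^{dt})`` and the Siler mortality
hazard, whose structure motivates the Moore form (substituting an
age-dependent mature hazard into the Siler model recovers Moore's
equation, see :func:`siler_equivalent_a2`).

All evaluators accept scalars or numpy arrays of ages and return floats or
arrays accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "MooreParams",
    "SilerParams",
    "IMAPParams",
    "IMAPShape",
    "CellTypeSpec",
    "DegeneratePeakError",
    "moore_performance",
    "siler_hazard",
    "siler_equivalent_a2",
    "imap_growth_rate",
    "imap_senescence",
    "imap_performance",
    "imap_reduced",
    "nondimensionalize",
    "redimensionalize",
    "asymptotic_population",
    "peak_location",
    "peak_age",
    "normalized_peak",
    "normalized_peak_ratio",
    "time_constant",
    "multitype_performance",
]

# Maximum exponent fed to np.exp during model evaluation; keeps optimizer
# excursions from producing inf without changing values in the sane domain.
_EXP_CAP = 700.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"parameter {name!r} must be finite and > 0, got {value!r}")


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"parameter {name!r} must be finite and >= 0, got {value!r}")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MooreParams:
    """Parameters of Moore's double-exponential age-performance curve.

    ``a`` and ``c`` are amplitudes (performance units) of the growth and
    decline terms; ``b`` and ``d`` are the corresponding rate constants
    (1/year).  All four constants are strictly positive.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        _require_positive(a=self.a, b=self.b, c=self.c, d=self.d)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)

    names = ("a", "b", "c", "d")


@dataclass(frozen=True)
class SilerParams:
    """Parameters of the Siler three-component mortality hazard.

    ``a1, b1`` govern the immature hazard (decaying exponential), ``a2`` is
    the constant mature hazard, and ``a3, b3`` govern the senescent hazard
    (growing exponential).  All non-negative.
    """

    a1: float
    b1: float
    a2: float
    a3: float
    b3: float

    def __post_init__(self) -> None:
        _require_nonnegative(a1=self.a1, b1=self.b1, a2=self.a2, a3=self.a3, b3=self.b3)


@dataclass(frozen=True)
class IMAPParams:
    """Dimensional IMAP1 parameters.

    ``scale`` is the product beta0*N0 (baseline functionality times baseline
    cell count, in performance units), ``alpha0`` the initial cell-population
    growth rate (1/year), ``alphar`` the strength of growth saturation
    (1/year), ``betar`` the strength of functionality decline (1/year), and
    ``td`` the time of death (years).  The age axis is anchored at t0 = 0.
    """

    scale: float
    alpha0: float
    alphar: float
    betar: float
    td: float

    def __post_init__(self) -> None:
        _require_positive(
            scale=self.scale, alpha0=self.alpha0, alphar=self.alphar,
            betar=self.betar, td=self.td,
        )


@dataclass(frozen=True)
class IMAPShape:
    """Dimensionless IMAP1 shape parameters.

    ``alpha0_star = alpha0*td``, ``alphar_star = alphar*td`` and
    ``betar_star = betar*td`` control the shape of the reduced curve
    ``x(u)`` on the unit lifespan ``u = t/td``; ``td`` (years) is retained
    for redimensionalization and ``scale_inf = beta0*N_inf`` (performance
    units) is the normalizing amplitude of the asymptotic form.
    """

    alpha0_star: float
    alphar_star: float
    betar_star: float
    td: float
    scale_inf: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            alpha0_star=self.alpha0_star, alphar_star=self.alphar_star,
            betar_star=self.betar_star, td=self.td, scale_inf=self.scale_inf,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.scale_inf, self.alpha0_star, self.alphar_star, self.betar_star, self.td],
            dtype=float,
        )

    names = ("scale_inf", "alpha0_star", "alphar_star", "betar_star", "td")

    def with_td(self, td: float) -> "IMAPShape":
        """Same dimensionless shape attached to a different lifespan."""
        return replace(self, td=td)


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type in the general multi-type performance model.

    ``phi`` is the contribution per cell (performance units per cell),
    ``n0`` the initial population, ``growth_rate_fn`` the time-dependent
    growth rate alpha_i(t) (1/year) and ``senescence_fn`` the functionality
    fraction beta_i(t).  ``growth_rate_integral``, when supplied, must
    return the cumulative integral of alpha_i from 0 to t; otherwise the
    integral is evaluated by adaptive quadrature.
    """

    phi: float
    n0: float
    growth_rate_fn: Callable[[float], float]
    senescence_fn: Callable[[np.ndarray], np.ndarray]
    growth_rate_integral: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi):
            raise ValueError("phi must be finite")
        if not np.isfinite(self.n0) or self.n0 < 0:
            raise ValueError("n0 must be finite and >= 0")


class DegeneratePeakError(ValueError):
    """Raised when the reduced curve has no interior maximum on (0, 1).

    ``boundary`` reports the argmax boundary (0.0: the curve is decreasing
    from birth onward).
    """

    def __init__(self, boundary: float, message: str):
        super().__init__(message)
        self.boundary = boundary


# ---------------------------------------------------------------------------
# Reference models
# ---------------------------------------------------------------------------


def _with_clamp(raw: np.ndarray, clamp: bool, return_clamped: bool, scalar: bool):
    clamped_mask = raw < 0.0
    out = np.where(clamped_mask, 0.0, raw) if clamp else raw
    if scalar:
        out = float(out)
        clamped_mask = bool(clamped_mask)
    if return_clamped:
        return out, clamped_mask
    return out


def moore_performance(t, p: MooreParams, *, clamp: bool = True, return_clamped: bool = False):
    """Moore's curve ``a(1 - e^{-bt}) + c(1 - e^{dt})`` at age ``t`` (years).

    Negative raw values are clamped to 0 by default (performance is
    non-negative); pass ``return_clamped=True`` to also obtain a mask
    reporting where clamping occurred, or ``clamp=False`` for the raw value
    (used internally by the least-squares objective).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    raw = p.a * (-np.expm1(-p.b * t)) + p.c * (-np.expm1(np.minimum(p.d * t, _EXP_CAP)))
    return _with_clamp(raw, clamp, return_clamped, scalar)


def siler_hazard(t, p: SilerParams):
    """Siler total hazard ``a1 e^{-b1 t} + a2 + a3 e^{b3 t}`` at age ``t``."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    q = p.a1 * np.exp(-p.b1 * t) + p.a2 + p.a3 * np.exp(np.minimum(p.b3 * t, _EXP_CAP))
    return float(q) if scalar else q


def siler_equivalent_a2(t, a1: float, b1: float, a3: float, b3: float):
    """Age-dependent mature hazard that turns the Siler form into Moore's.

    Returns ``a2(t) = a1 + a3 - 2 a1 e^{-b1 t} - 2 a3 e^{b3 t}``.  With this
    substitution the Siler hazard collapses to
    ``a1 (1 - e^{-b1 t}) + a3 (1 - e^{b3 t})``, i.e. Moore's curve with
    ``(a, b, c, d) = (a1, b1, a3, b3)``.
    """
    _require_nonnegative(a1=a1, b1=b1, a3=a3, b3=b3)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    out = a1 + a3 - 2.0 * a1 * np.exp(-b1 * t) - 2.0 * a3 * np.exp(np.minimum(b3 * t, _EXP_CAP))
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# IMAP1 building blocks
# ---------------------------------------------------------------------------


def imap_growth_rate(t, alpha0: float, alphar: float):
    """Cell-population growth rate ``alpha(t) = alpha0 e^{-alphar t}``."""
    _require_positive(alpha0=alpha0, alphar=alphar)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    out = alpha0 * np.exp(-alphar * t)
    return float(out) if scalar else out


def imap_senescence(t, beta0: float, betar: float, td: float):
    """Average cell functionality ``beta(t) = beta0 (1 - e^{betar (t - td)})``.

    Zero at ``t = td`` and negative beyond; callers clamp at the performance
    level, not here.
    """
    _require_positive(beta0=beta0, betar=betar, td=td)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    out = beta0 * (-np.expm1(np.minimum(betar * (t - td), _EXP_CAP)))
    return float(out) if scalar else out


def imap_performance(t, p: IMAPParams, *, clamp: bool = True, return_clamped: bool = False):
    """IMAP1 performance curve at age ``t`` (years).

    ``P(t) = scale * exp((alpha0/alphar)(1 - e^{-alphar t})) * (1 - e^{betar (t - td)})``
    with ``scale = beta0 * N0``.  The curve vanishes at ``t = td``; beyond
    the time of death the raw value is negative and is clamped to 0 by
    default (with an optional mask, as in :func:`moore_performance`).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    growth = np.exp((p.alpha0 / p.alphar) * (-np.expm1(-p.alphar * t)))
    decline = -np.expm1(np.minimum(p.betar * (t - p.td), _EXP_CAP))
    raw = p.scale * growth * decline
    return _with_clamp(raw, clamp, return_clamped, scalar)


def imap_reduced(u, s: IMAPShape, *, clamp: bool = True, return_clamped: bool = False):
    """Reduced dimensionless IMAP1 curve ``x(u)`` on the unit lifespan.

    ``x(u) = exp(-(alpha0*/alphar*) e^{-alphar* u}) * (1 - e^{betar* (u - 1)})``,
    with ``u = t/td`` and ``x = P / (beta0 N_inf)``.  Values at ``u > 1``
    are clamped to 0 (with flag) by default.
    """
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 0
    raw = np.exp(-(s.alpha0_star / s.alphar_star) * np.exp(-s.alphar_star * u)) * (
        -np.expm1(np.minimum(s.betar_star * (u - 1.0), _EXP_CAP))
    )
    return _with_clamp(raw, clamp, return_clamped, scalar)


def imap_curve(t, s: IMAPShape, *, clamp: bool = True):
    """Dimensional curve from a shape: ``scale_inf * x(t/td)``."""
    t = np.asarray(t, dtype=float)
    return s.scale_inf * imap_reduced(t / s.td, s, clamp=clamp)


def nondimensionalize(p: IMAPParams) -> IMAPShape:
    """Map dimensional parameters to the reduced shape.

    ``alpha0* = alpha0 td``, ``alphar* = alphar td``, ``betar* = betar td``;
    the normalizing amplitude is ``scale_inf = scale * e^{alpha0/alphar}``
    (the asymptotic-population form of the curve).
    """
    return IMAPShape(
        alpha0_star=p.alpha0 * p.td,
        alphar_star=p.alphar * p.td,
        betar_star=p.betar * p.td,
        td=p.td,
        scale_inf=p.scale * np.exp(p.alpha0 / p.alphar),
    )


def redimensionalize(s: IMAPShape) -> IMAPParams:
    """Inverse of :func:`nondimensionalize`."""
    ratio = s.alpha0_star / s.alphar_star
    return IMAPParams(
        scale=s.scale_inf * np.exp(-ratio),
        alpha0=s.alpha0_star / s.td,
        alphar=s.alphar_star / s.td,
        betar=s.betar_star / s.td,
        td=s.td,
    )


def asymptotic_population(n0: float, alpha0: float, alphar: float) -> float:
    """Asymptotic cell count ``N_inf = N0 e^{alpha0/alphar}`` (always >= N0)."""
    _require_positive(n0=n0, alpha0=alpha0, alphar=alphar)
    return n0 * np.exp(alpha0 / alphar)


# ---------------------------------------------------------------------------
# Derived quantities: peak age, normalized peak, time constant
# ---------------------------------------------------------------------------


def _stationarity(u: float, a0s: float, ars: float, brs: float) -> float:
    # d ln x / du = a0s e^{-ars u} - brs e^{brs(u-1)} / (1 - e^{brs(u-1)})
    #             = a0s e^{-ars u} - brs / expm1(brs (1 - u))
    return a0s * np.exp(-ars * u) - brs / np.expm1(brs * (1.0 - u))


_GRID_N = 1_000_001


def _grid_peak(s: IMAPShape) -> float:
    u = np.linspace(0.0, 1.0, _GRID_N)
    return float(u[np.argmax(imap_reduced(u, s))])


def peak_location(s: IMAPShape, *, xtol: float = 1e-10) -> float:
    """Location ``u*`` of the maximum of the reduced curve on (0, 1).

    The maximizer solves the stationarity condition of ``d ln x / du = 0``:
    ``alpha0* e^{-alphar* u} = betar* e^{betar*(u-1)} / (1 - e^{betar*(u-1)})``.
    The left side (growth pull) decreases monotonically while the right side
    (senescence drag) increases to infinity at ``u = 1``, so an interior
    maximum exists iff the growth pull dominates at ``u = 0``; it is then
    unique and located by bracketed root-finding (dense-grid maximization as
    fallback).

    Raises
    ------
    DegeneratePeakError
        If the curve is monotone decreasing on [0, 1] (no interior peak);
        the exception carries the boundary argmax.
    """
    a0s, ars, brs = s.alpha0_star, s.alphar_star, s.betar_star
    lo, hi = 1e-12, 1.0 - 1e-12
    g_lo = _stationarity(lo, a0s, ars, brs)
    if g_lo <= 0.0:
        raise DegeneratePeakError(
            0.0,
            "reduced curve has no interior maximum: growth pull does not exceed "
            "senescence drag at u=0 (argmax at the u=0 boundary)",
        )
    try:
        return float(optimize.brentq(_stationarity, lo, hi, args=(a0s, ars, brs), xtol=xtol))
    except (ValueError, RuntimeError):
        return _grid_peak(s)


def peak_age(s: IMAPShape) -> float:
    """Age of peak performance in years: ``u* * td``."""
    return peak_location(s) * s.td


def normalized_peak(s: IMAPShape) -> float:
    """Age of peak performance as a fraction of the lifespan (equals ``u*``).

    Depends only on the dimensionless shape ``(alpha0*, alphar*, betar*)``,
    not on ``td``.
    """
    return peak_location(s)


def normalized_peak_ratio(peak_age_years: float, td: float) -> float:
    """Normalized peak from already-known peak age and lifespan values."""
    _require_positive(peak_age_years=peak_age_years, td=td)
    return peak_age_years / td


def time_constant(s: IMAPShape) -> float:
    """Growth time constant ``tau = 1/alphar = td / alphar*`` in years."""
    return s.td / s.alphar_star


# ---------------------------------------------------------------------------
# General multi-type model
# ---------------------------------------------------------------------------


def _cumulative_growth_integral(fn: Callable[[float], float], t_grid: np.ndarray) -> np.ndarray:
    """Cumulative integral of a growth rate over [0, t] at each grid age."""
    edges = np.concatenate([[0.0], t_grid])
    pieces = [
        integrate.quad(fn, edges[i], edges[i + 1], limit=200)[0]
        for i in range(len(t_grid))
    ]
    return np.cumsum(pieces)


def multitype_performance(t_grid: Sequence[float], types: Sequence[CellTypeSpec]) -> np.ndarray:
    """Performance of a mixture of non-interacting cell types.

    Each population grows as ``dN_i/dt = alpha_i(t) N_i(t)``, i.e.
    ``N_i(t) = N_i(0) exp(integral of alpha_i over [0, t])``, and the summed
    performance is ``P(t) = sum_i phi_i beta_i(t) N_i(t)`` on the given age
    grid.  The growth integral uses the supplied closed form when available
    and adaptive quadrature otherwise.
    """
    if len(types) == 0:
        raise ValueError("at least one cell type is required")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid[0] < 0 or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted ascending with ages >= 0")

    total = np.zeros_like(t_grid)
    for spec in types:
        if spec.growth_rate_integral is not None:
            cumint = np.asarray(spec.growth_rate_integral(t_grid), dtype=float)
        else:
            cumint = _cumulative_growth_integral(spec.growth_rate_fn, t_grid)
        n_t = spec.n0 * np.exp(cumint)
        assert np.all(n_t >= 0.0), "population must remain non-negative"
        beta_t = np.asarray(spec.senescence_fn(t_grid), dtype=float)
        total += spec.phi * beta_t * n_t
    return total
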