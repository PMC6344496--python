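"""Nonlinear least-squares fitting of age-performance curves.

Both models are fitted to an :class:`~ageperf.envelope.EnvelopeSeries` by
trust-region least squares with positivity bounds.  The IMAP1 curve is
fitted in its asymptotic, nondimensionalized parameterization
``(scale_inf, alpha0*, alphar*, betar*, td)`` — the form whose normalizing
amplitude is ``beta0 * N_inf`` — which conditions the search space much
better than the raw dimensional parameters and converges faster.

Goodness of fit is summarized by R², adjusted R², RMSE and the
small-sample corrected Akaike criterion (AICc); two fitted curves are
additionally compared by dynamic time warping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .envelope import EnvelopeSeries
from .models import IMAPShape, MooreParams, imap_curve, moore_performance

__all__ = [
    "FitResult",
    "ComparisonReport",
    "fit_imap",
    "fit_moore",
    "goodness_of_fit",
    "dtw_distance",
    "compare_models",
]

MODEL_MOORE = "moore"
MODEL_IMAP1 = "imap1"


@dataclass
class FitResult:
    """Estimates, covariance and diagnostics for one model on one envelope.

    ``params`` is the typed parameter object (:class:`MooreParams` or
    :class:`IMAPShape`); ``estimates`` the same values as a vector in
    ``param_names`` order; ``covariance`` the asymptotic covariance from
    the Jacobian at the optimum (residual variance times the inverse
    Gauss-Newton Hessian).
    """

    model: str
    params: Any
    param_names: tuple[str, ...]
    estimates: np.ndarray
    covariance: np.ndarray
    residuals: np.ndarray
    metrics: dict[str, float | None]
    converged: bool
    n_obs: int
    ages: np.ndarray
    observed: np.ndarray
    message: str = ""
    init: np.ndarray | None = None

    def predict(self, ages, *, clamp: bool = True) -> np.ndarray:
        """Fitted curve on an arbitrary age grid (years)."""
        if self.model == MODEL_MOORE:
            return moore_performance(ages, self.params, clamp=clamp)
        return imap_curve(ages, self.params, clamp=clamp)

    def to_report(self) -> dict[str, Any]:
        """JSON-ready summary (named estimates, row-major covariance)."""
        return {
            "model": self.model,
            "param_names": list(self.param_names),
            "estimates": {n: float(v) for n, v in zip(self.param_names, self.estimates, strict=True)},
            "covariance": [[float(v) for v in row] for row in self.covariance],
            "metrics": {k: (None if v is None else float(v)) for k, v in self.metrics.items()},
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "message": self.message,
        }


@dataclass
class ComparisonReport:
    """Side-by-side metrics for a Moore and an IMAP1 fit on one envelope."""

    metrics_moore: dict[str, float | None]
    metrics_imap: dict[str, float | None]
    delta_aicc: float | None  # AICc(moore) - AICc(imap1); positive favors IMAP1
    dtw_distance: float
    preferred_model: str
    grid: np.ndarray = field(repr=False, default=None)

    def to_report(self) -> dict[str, Any]:
        return {
            "metrics_moore": self.metrics_moore,
            "metrics_imap1": self.metrics_imap,
            "delta_aicc": self.delta_aicc,
            "dtw_distance": float(self.dtw_distance),
            "preferred_model": self.preferred_model,
        }


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def goodness_of_fit(observed, fitted, n_params: int) -> dict[str, float | None]:
    """R², adjusted R², RMSE and AICc for a fitted curve.

    ``R² = 1 - SSres/SStot``; ``adj_R² = 1 - (1 - R²)(n-1)/(n-p-1)`` with
    ``p = n_params``; ``RMSE = sqrt(SSres/n)``.  AICc counts the error
    variance as an extra estimated parameter (``p = n_params + 1``):
    ``AICc = n ln(SSres/n) + 2p + 2p(p+1)/(n-p-1)``, reported as ``None``
    when the correction denominator is not positive.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = observed.size
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance; R-squared undefined")
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1) if n > n_params + 1 else None
    rmse = float(np.sqrt(ss_res / n))
    p = n_params + 1  # count the error variance
    if n - p - 1 > 0 and ss_res > 0:
        aicc = n * np.log(ss_res / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)
    elif n - p - 1 > 0 and ss_res == 0.0:
        aicc = -np.inf  # perfect fit
    else:
        aicc = None
    return {"r2": r2, "adj_r2": adj_r2, "rmse": rmse, "aicc": aicc}


# ---------------------------------------------------------------------------
# Core least-squares driver
# ---------------------------------------------------------------------------


def _jitter_starts(init, bounds, n_starts, seed):
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    starts = [np.asarray(init, dtype=float)]
    for _ in range(n_starts - 1):
        jittered = init * np.exp(rng.normal(0.0, 0.25, size=len(init)))
        starts.append(np.clip(jittered, lo * 1.000001, hi * 0.999999))
    return starts


def _least_squares(residual_fn, init, bounds, n_starts, seed):
    best = None
    for start in _jitter_starts(init, bounds, n_starts, seed):
        try:
            res = optimize.least_squares(
                residual_fn, start, bounds=bounds, method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20_000,
            )
        except Exception:  # singular step, bad start — try the next one
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best


def _covariance(jac: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(np.sum(residuals**2)) / dof
    jtj = jac.T @ jac
    cov = s2 * np.linalg.pinv(jtj)
    return 0.5 * (cov + cov.T)  # enforce exact symmetry


def _build_result(model, make_params, names, env, res, init) -> FitResult:
    residuals = res.fun  # model - observed at the optimum
    fitted = env.values + residuals
    metrics = goodness_of_fit(env.values, fitted, n_params=len(names))
    cov = _covariance(res.jac, residuals)
    params = make_params(res.x)
    return FitResult(
        model=model,
        params=params,
        param_names=names,
        estimates=res.x.copy(),
        covariance=cov,
        residuals=residuals.copy(),
        metrics=metrics,
        converged=bool(res.success),
        n_obs=len(env),
        ages=env.ages.copy(),
        observed=env.values.copy(),
        message=res.message,
        init=np.asarray(init, dtype=float),
    )


def _check_envelope(env: EnvelopeSeries, n_min: int) -> None:
    if len(env) < n_min:
        raise ValueError(
            f"envelope has {len(env)} points; at least {n_min} are required "
            "to identify the model"
        )
    if np.ptp(env.values) == 0.0:
        raise ValueError("degenerate envelope: all values identical")


def fit_imap(
    env: EnvelopeSeries,
    init: IMAPShape | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    *,
    weights: np.ndarray | None = None,
    n_starts: int = 1,
    seed: int = 0,
) -> FitResult:
    """Fit the IMAP1 curve ``scale_inf * x(t/td)`` to an envelope.

    Minimizes the (optionally weighted) sum of squared deviations over
    ``(scale_inf, alpha0*, alphar*, betar*, td)`` with positivity bounds
    and ``td`` constrained above the oldest observed age.  Deterministic
    given ``init`` (and ``seed`` when ``n_starts > 1`` enables jittered
    multi-start).

    Default initialization places the shape parameters in the range typical
    of human series (``alpha0* = 30``, ``alphar* = 20``, ``betar* = 3``)
    with ``td = 1.2 * max(age)`` and ``scale_inf = 1.05 * max(value)``.
    """
    _check_envelope(env, n_min=6)
    t, y = env.ages, env.values
    max_age, max_val = float(t.max()), float(y.max())
    if init is None:
        x0 = np.array([1.05 * max_val, 30.0, 20.0, 3.0, 1.2 * max_age])
    else:
        x0 = init.as_array()
    if bounds is None:
        lo = np.array([1e-8 * max_val, 1e-6, 1e-6, 1e-6, max_age * (1.0 + 1e-9)])
        hi = np.array([1e4 * max_val, 1e4, 1e4, 1e4, 50.0 * max_age])
        bounds = (lo, hi)
    x0 = np.clip(x0, bounds[0], bounds[1])
    w = np.sqrt(np.asarray(weights, dtype=float)) if weights is not None else 1.0

    def residual_fn(theta):
        scale_inf, a0s, ars, brs, td = theta
        shape = IMAPShape(a0s, ars, brs, td, scale_inf)
        return w * (imap_curve(t, shape, clamp=False) - y)

    res = _least_squares(residual_fn, x0, bounds, n_starts, seed)
    make = lambda x: IMAPShape(alpha0_star=x[1], alphar_star=x[2], betar_star=x[3],
                               td=x[4], scale_inf=x[0])
    return _build_result(MODEL_IMAP1, make, IMAPShape.names, env, res, x0)


def fit_moore(
    env: EnvelopeSeries,
    init: MooreParams | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    *,
    weights: np.ndarray | None = None,
    n_starts: int = 1,
    seed: int = 0,
) -> FitResult:
    """Fit Moore's curve ``a(1-e^{-bt}) + c(1-e^{dt})`` to an envelope.

    Four positive parameters; same driver and conventions as
    :func:`fit_imap`.
    """
    _check_envelope(env, n_min=5)
    t, y = env.ages, env.values
    max_age, max_val = float(t.max()), float(y.max())
    age_at_max = float(t[np.argmax(y)])
    if init is None:
        x0 = np.array([1.1 * max_val, 3.0 / max(age_at_max, 1e-6),
                       0.02 * max_val, 1.0 / max_age])
    else:
        x0 = init.as_array()
    if bounds is None:
        lo = np.array([1e-8 * max_val, 1e-8 / max_age, 1e-10 * max_val, 1e-8 / max_age])
        hi = np.array([1e4 * max_val, 1e4 / max_age, 1e4 * max_val, 50.0 / max_age])
        bounds = (lo, hi)
    x0 = np.clip(x0, bounds[0], bounds[1])
    w = np.sqrt(np.asarray(weights, dtype=float)) if weights is not None else 1.0

    def residual_fn(theta):
        a, b, c, d = theta
        raw = a * (-np.expm1(-b * t)) + c * (-np.expm1(np.minimum(d * t, 700.0)))
        return w * (raw - y)

    res = _least_squares(residual_fn, x0, bounds, n_starts, seed)
    make = lambda x: MooreParams(a=x[0], b=x[1], c=x[2], d=x[3])
    return _build_result(MODEL_MOORE, make, MooreParams.names, env, res, x0)


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------


def dtw_distance(curve_a, curve_b) -> float:
    """Classic dynamic-time-warping distance between two curves.

    Absolute-difference local cost, symmetric step pattern (match, insert,
    delete each paying the local cost), no warping window; returns the
    accumulated cost of the optimal monotone alignment.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty sequences")
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((a.size, b.size), np.inf)
    acc[0, 0] = cost[0, 0]
    for j in range(1, b.size):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, a.size):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        row_prev, row_cur = acc[i - 1], acc[i]
        for j in range(1, b.size):
            row_cur[j] = cost[i, j] + min(row_prev[j - 1], row_prev[j], row_cur[j - 1])
    return float(acc[-1, -1])


def compare_models(
    fit_m: FitResult,
    fit_i: FitResult,
    grid: np.ndarray | None = None,
) -> ComparisonReport:
    """Assemble a model-comparison report for two fits of the same envelope.

    The preferred model is the one with the lower AICc (ties go to the
    model with fewer parameters, i.e. Moore).  DTW is computed between the
    two fitted curves on ``grid`` (default: the envelope's own ages).
    """
    if fit_m.model != MODEL_MOORE or fit_i.model != MODEL_IMAP1:
        raise ValueError("expected a Moore fit and an IMAP1 fit, in that order")
    if fit_m.n_obs != fit_i.n_obs or not np.allclose(fit_m.ages, fit_i.ages):
        raise ValueError("fits target different envelopes; comparison undefined")
    if grid is None:
        grid = fit_m.ages
    grid = np.asarray(grid, dtype=float)
    dtw = dtw_distance(fit_m.predict(grid), fit_i.predict(grid))
    aicc_m, aicc_i = fit_m.metrics.get("aicc"), fit_i.metrics.get("aicc")
    delta = None if aicc_m is None or aicc_i is None else aicc_m - aicc_i
    if delta is None:
        preferred = MODEL_IMAP1 if fit_i.metrics["r2"] > fit_m.metrics["r2"] else MODEL_MOORE
    else:
        preferred = MODEL_IMAP1 if delta > 0 else MODEL_MOORE
    return ComparisonReport(
        metrics_moore=fit_m.metrics,
        metrics_imap=fit_i.metrics,
        delta_aicc=delta,
        dtw_distance=dtw,
        preferred_model=preferred,
        grid=grid,
    )
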