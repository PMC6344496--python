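"""Monte-Carlo credibility envelopes around fitted performance curves.

Parameter vectors are drawn from the multivariate normal centered at the
least-squares estimates with the fitted covariance; the band reported is
the pointwise min/max envelope containing *all* drawn curves (a quantile
band is available as an option but is not the primary definition).  For
the IMAP1 model the explicit time-of-death parameter forces every drawn
curve to zero at its own ``td``, so the envelope closes at advanced ages;
Moore's curve has no such parameter and its envelope widens instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .fitting import MODEL_IMAP1, MODEL_MOORE, FitResult

__all__ = ["ParameterDraws", "CredibilityEnvelope", "sample_parameters", "credibility_envelope"]

DEFAULT_N_DRAWS = 100_000
_BATCH = 20_000


@dataclass
class ParameterDraws:
    """Accepted parameter draws plus sampling bookkeeping."""

    model: str
    param_names: tuple[str, ...]
    draws: np.ndarray  # (n_draws, n_params)
    n_rejected: int
    seed: int

    def __len__(self) -> int:
        return int(self.draws.shape[0])


@dataclass
class CredibilityEnvelope:
    """Pointwise lower/upper bounds over an age grid from Monte-Carlo draws."""

    age_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_draws: int
    n_rejected: int
    seed: int
    clamped: bool = True

    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self, fitted: np.ndarray | None = None):
        import pandas as pd

        data: dict[str, Any] = {"age": self.age_grid}
        if fitted is not None:
            data["fitted"] = np.asarray(fitted, dtype=float)
        data["lower"] = self.lower
        data["upper"] = self.upper
        return pd.DataFrame(data)

    def metadata(self) -> dict[str, Any]:
        return {
            "n_draws": int(self.n_draws),
            "n_rejected": int(self.n_rejected),
            "seed": int(self.seed),
            "clamped": bool(self.clamped),
        }


def sample_parameters(fit: FitResult, n_draws: int, seed: int) -> ParameterDraws:
    """Draw parameter vectors from the fit's multivariate normal.

    Draws violating the positivity domain of the model parameters are
    rejected and redrawn so exactly ``n_draws`` valid vectors are returned;
    the rejection count is reported.  Aborts if more than half of an
    initial batch is rejected — the covariance is then inconsistent with
    the parameter domain and the normal approximation is meaningless.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cov = np.asarray(fit.covariance, dtype=float)
    if cov.shape != (len(fit.estimates), len(fit.estimates)):
        raise ValueError("covariance shape does not match the number of parameters")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, float(np.abs(cov).max()))):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8 * max(1.0, float(eigvals.max())):
        raise ValueError("covariance must be positive semidefinite")

    rng = np.random.default_rng(seed)
    mean = np.asarray(fit.estimates, dtype=float)
    accepted: list[np.ndarray] = []
    n_accepted = 0
    n_rejected = 0
    first_batch_checked = False
    while n_accepted < n_draws:
        batch = min(_BATCH, max(n_draws - n_accepted, 1000))
        cand = rng.multivariate_normal(mean, cov, size=batch, method="svd")
        ok = np.all(cand > 0.0, axis=1)
        n_rejected += int(batch - ok.sum())
        if not first_batch_checked:
            first_batch_checked = True
            if ok.sum() < 0.5 * batch:
                raise RuntimeError(
                    f"rejection rate {1 - ok.sum() / batch:.1%} exceeds 50%: the fitted "
                    "covariance is inconsistent with parameter positivity"
                )
        kept = cand[ok]
        accepted.append(kept)
        n_accepted += kept.shape[0]
    draws = np.concatenate(accepted, axis=0)[:n_draws]
    return ParameterDraws(
        model=fit.model,
        param_names=fit.param_names,
        draws=draws,
        n_rejected=n_rejected,
        seed=seed,
    )


def _eval_curves(model: str, draws: np.ndarray, age_grid: np.ndarray, clamp: bool) -> np.ndarray:
    """Curve matrix (n_draws, n_ages) for a block of parameter draws."""
    t = age_grid[None, :]
    if model == MODEL_MOORE:
        a, b, c, d = (draws[:, k][:, None] for k in range(4))
        raw = a * (-np.expm1(-b * t)) + c * (-np.expm1(np.minimum(d * t, 700.0)))
    elif model == MODEL_IMAP1:
        scale_inf, a0s, ars, brs, td = (draws[:, k][:, None] for k in range(5))
        u = t / td
        raw = scale_inf * np.exp(-(a0s / ars) * np.exp(-ars * u)) * (
            -np.expm1(np.minimum(brs * (u - 1.0), 700.0))
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    if clamp:
        raw = np.maximum(raw, 0.0)
    return raw


def credibility_envelope(
    draws: ParameterDraws,
    age_grid,
    *,
    clamp: bool = True,
    quantiles: tuple[float, float] | None = None,
) -> CredibilityEnvelope:
    """Pointwise band over the model curves of all parameter draws.

    By default the band is the min/max envelope containing every drawn
    curve, clamped at zero.  Passing ``quantiles=(0.025, 0.975)`` gives a
    central quantile band instead; ``clamp=False`` keeps raw (possibly
    negative) curve values — useful when diagnosing late-age divergence of
    models without a death-time parameter.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    if age_grid.size == 0:
        raise ValueError("age grid must be non-empty")
    if len(draws) < 1:
        raise ValueError("at least one draw is required")
    lower = np.full(age_grid.size, np.inf)
    upper = np.full(age_grid.size, -np.inf)
    q_blocks: list[np.ndarray] = []
    for start in range(0, len(draws), _BATCH):
        block = _eval_curves(draws.model, draws.draws[start:start + _BATCH], age_grid, clamp)
        if quantiles is None:
            lower = np.minimum(lower, block.min(axis=0))
            upper = np.maximum(upper, block.max(axis=0))
        else:
            q_blocks.append(block)
    if quantiles is not None:
        stacked = np.concatenate(q_blocks, axis=0)
        lower = np.quantile(stacked, quantiles[0], axis=0)
        upper = np.quantile(stacked, quantiles[1], axis=0)
    return CredibilityEnvelope(
        age_grid=age_grid,
        lower=lower,
        upper=upper,
        n_draws=len(draws),
        n_rejected=draws.n_rejected,
        seed=draws.seed,
        clamped=clamp,
    )
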