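"""AIC-based comparison of dose-response shapes, with R² validation.

Shapes are compared on three fit variants:

1. **outcome variant** — residuals between predicted outcome-class
   probabilities ``f_k(θ̂)`` and the observed relative frequencies
   (``n + 1`` observations);
2. **parameter variant** — residuals between the shape's dose-response curve
   ``r_i(θ)`` and the shape-free (agnostic) point estimates ``r̂_i``
   (``n`` observations);
3. **weighted parameter variant** — as (2) with each residual divided by
   the parameter's uncertainty scale, taken as the reciprocal of its
   normalised local-sensitivity score: parameters that barely move the fit
   objective are the ones the data constrain least, so their residuals are
   discounted.

Each variant's AIC is ``n_obs · log(RSS/n_obs) + 2k`` (natural log); the
lowest AIC wins.  The selected model is validated by the coefficient of
determination on the parameter variant, unweighted and weighted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from scipy.optimize import minimize

from .exceptions import FitError, ValidationError
from .inference import (
    FitConfig,
    ObservedCounts,
    _box_bounds,
    _box_to_theta,
    _draw_start,
    l2_fit,
    local_sensitivity,
)
from .shapes import ShapeSpec, degrees_of_freedom, expand

__all__ = [
    "aic",
    "r_squared",
    "compare_models",
    "residual_diagnostics",
    "SelectionReport",
    "SelectionRow",
    "ResidualDiagnostics",
]


def aic(rss: float, n_obs: int, k_params: int) -> float:
    """Akaike information criterion for a least-squares fit: n·log(RSS/n) + 2k."""
    if n_obs < 1:
        raise ValidationError("n_obs must be >= 1")
    if k_params < 0:
        raise ValidationError("k_params must be >= 0")
    if rss < 0:
        raise ValidationError("RSS must be non-negative")
    if rss == 0.0:
        warnings.warn("AIC of a perfect fit (RSS = 0) is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return n_obs * math.log(rss / n_obs) + 2 * k_params


def r_squared(observed, predicted, uncertainty=None) -> float:
    """Coefficient of determination 1 − RSS/TSS.

    With ``uncertainty`` given (one positive scale per point), each residual
    and each deviation from the (precision-weighted) mean is divided by its
    scale before squaring; the result is invariant under uniform rescaling
    of the uncertainty vector.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted must have equal length")
    if uncertainty is None:
        rss = float(np.sum((obs - pred) ** 2))
        tss = float(np.sum((obs - obs.mean()) ** 2))
    else:
        u = np.asarray(uncertainty, dtype=float)
        if u.shape != obs.shape or np.any(u <= 0):
            raise ValidationError("uncertainty scales must be positive, one per point")
        w = 1.0 / u**2
        wmean = float(np.sum(w * obs) / np.sum(w))
        rss = float(np.sum(((obs - pred) / u) ** 2))
        tss = float(np.sum(((obs - wmean) / u) ** 2))
    if tss <= 0:
        raise ValidationError("total sum of squares is zero; R^2 undefined")
    return 1.0 - rss / tss


@dataclass(frozen=True)
class SelectionRow:
    model: str
    variant: int
    rss: float
    n_obs: int
    k_params: int
    aic: float
    best: bool


@dataclass(frozen=True)
class SelectionReport:
    """Per-model, per-variant AIC table plus validation of the winner."""

    rows: tuple[SelectionRow, ...]
    selected: str
    r2_unweighted: float
    r2_weighted: float
    residuals: np.ndarray = field(compare=False)
    agnostic_estimate: np.ndarray = field(compare=False)
    weights: np.ndarray = field(compare=False)

    def winner(self, variant: int) -> str:
        for row in self.rows:
            if row.variant == variant and row.best:
                return row.model
        raise KeyError(f"no rows for variant {variant}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "model": r.model,
                    "variant": r.variant,
                    "rss": r.rss,
                    "n_obs": r.n_obs,
                    "k_params": r.k_params,
                    "aic": r.aic,
                    "best": r.best,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "rows": self.to_frame().to_dict(orient="records"),
                "selected": self.selected,
                "r2_unweighted": self.r2_unweighted,
                "r2_weighted": self.r2_weighted,
            }
        )


def _curve_fit(
    kind: str,
    target: np.ndarray,
    weights: np.ndarray | None,
    n: int,
    cfg: FitConfig,
) -> tuple[tuple[float, ...], float]:
    """Least-squares fit of a shape's dose-response curve to target r-values."""
    w = np.ones(n) if weights is None else weights

    def objective(x: np.ndarray) -> float:
        theta = _box_to_theta(kind, x, n, cfg)
        curve = np.asarray(expand(ShapeSpec(kind, theta), n).r)
        return float(np.sum(w * (curve - target) ** 2))

    rng = np.random.default_rng(cfg.seed)
    bounds = _box_bounds(kind, n, cfg)
    best = None
    for _ in range(cfg.restarts):
        res = minimize(
            objective, _draw_start(kind, n, cfg, rng), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": cfg.maxiter},
        )
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"curve fit for {kind!r} failed from all starts")
    return _box_to_theta(kind, best.x, n, cfg), float(best.fun)


def compare_models(
    data: ObservedCounts,
    kinds: tuple[str, ...] = ("linear", "sigmoidal"),
    variants: tuple[int, ...] = (1, 2, 3),
    config: FitConfig | None = None,
    sensitivity_scale: float = 0.05,
    sensitivity_samples: int = 400,
) -> SelectionReport:
    """Fit every candidate shape under every variant and rank them by AIC.

    Fit failures for one candidate are annotated (an ``inf`` AIC row) rather
    than aborting the comparison.  The report's ``selected`` model is the
    variant-1 winner; its parameter-variant R² values (unweighted and
    sensitivity-weighted) validate the absolute quality of that choice.
    """
    cfg = config or FitConfig()
    n = data.n

    agnostic = l2_fit(data, "agnostic", cfg)
    rhat = np.asarray(agnostic.expanded.r)
    sens = local_sensitivity(
        agnostic.shape, data, scale=sensitivity_scale, samples=sensitivity_samples,
        seed=cfg.seed,
    )
    weights = sens.normalised()
    # exact ties in the monotone estimate leave a parameter with no feasible
    # one-sided perturbation and hence a zero score; floor those at the
    # smallest informative score so every residual keeps positive weight
    positive = weights[weights > 0]
    if positive.size:
        weights = np.where(weights > 0, weights, positive.min())
    else:
        weights = np.ones(n)

    rows: list[SelectionRow] = []
    curve_cache: dict[tuple[str, int], tuple[tuple[float, ...], float]] = {}
    for variant in variants:
        entries = []
        for kind in kinds:
            k_params = degrees_of_freedom(kind, n)
            try:
                if variant == 1:
                    rss = l2_fit(data, kind, cfg).l2_distance
                    n_obs = n + 1
                else:
                    w = None if variant == 2 else weights
                    theta, rss = _curve_fit(kind, rhat, w, n, cfg)
                    curve_cache[(kind, variant)] = (theta, rss)
                    n_obs = n
                entries.append((kind, rss, n_obs, k_params, aic(rss, n_obs, k_params)))
            except FitError:
                entries.append((kind, math.nan, 0, k_params, math.inf))
        best_aic = min(e[4] for e in entries)
        for kind, rss, n_obs, k_params, a in entries:
            rows.append(
                SelectionRow(
                    model=kind, variant=variant, rss=rss, n_obs=n_obs,
                    k_params=k_params, aic=a, best=(a == best_aic),
                )
            )

    selected = next(r.model for r in rows if r.variant == variants[0] and r.best)

    # validation of the selected model on the parameter variant
    theta2, _ = curve_cache.get((selected, 2)) or _curve_fit(selected, rhat, None, n, cfg)
    curve2 = np.asarray(expand(ShapeSpec(selected, theta2), n).r)
    r2_unw = r_squared(rhat, curve2)
    theta3, _ = curve_cache.get((selected, 3)) or _curve_fit(selected, rhat, weights, n, cfg)
    curve3 = np.asarray(expand(ShapeSpec(selected, theta3), n).r)
    r2_w = r_squared(rhat, curve3, uncertainty=1.0 / np.sqrt(weights))

    return SelectionReport(
        rows=tuple(rows),
        selected=selected,
        r2_unweighted=r2_unw,
        r2_weighted=r2_w,
        residuals=rhat - curve2,
        agnostic_estimate=rhat,
        weights=weights,
    )


@dataclass(frozen=True)
class ResidualDiagnostics:
    statistic: float
    p_value: float
    mean: float
    skew: float
    degenerate: bool


def residual_diagnostics(residuals) -> ResidualDiagnostics:
    """Shapiro-Wilk normality check plus location/shape summaries."""
    res = np.asarray(residuals, dtype=float)
    if res.size < 3:
        raise ValidationError("need at least 3 residuals for diagnostics")
    if np.allclose(res, res[0]):
        return ResidualDiagnostics(
            statistic=math.nan, p_value=math.nan, mean=float(res.mean()),
            skew=0.0, degenerate=True,
        )
    stat, p = scipy.stats.shapiro(res)
    return ResidualDiagnostics(
        statistic=float(stat), p_value=float(p), mean=float(res.mean()),
        skew=float(scipy.stats.skew(res)), degenerate=False,
    )
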