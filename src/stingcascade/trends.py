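"""How the dose-response to alarm pheromone changes with group size.

For every group size the linear dose-response curve is fitted independently;
the fitted slope (pheromone recruitment strength), intercept (basal sting
probability of the linear fit) and the shape-free estimate of ``r_0`` are
then each tested for a monotone association with group size using Pearson's
correlation.  A negative slope trend is the signature of nestmates curbing
pheromone recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .cascade import OutcomeDistribution
from .exceptions import ValidationError
from .inference import FitConfig, FitResult, ObservedCounts, l2_fit, log_likelihood
from .shapes import ShapeSpec, expand

__all__ = ["fit_per_group_size", "trend_test", "analyse_trends", "TrendResult"]


def _bernoulli_fit(data: ObservedCounts, kind: str) -> FitResult:
    """Closed-form fit for a single bee: r_0 is the observed sting frequency."""
    r0 = data.counts[1] / data.total
    theta = {"agnostic": (r0,), "linear": (r0, 0.0), "sigmoidal": (r0, r0, 1.0, 1.0)}[kind]
    shape = ShapeSpec(kind, theta)
    expanded = expand(shape, 1)
    predicted = OutcomeDistribution((1.0 - r0, r0))
    freq = data.frequencies()
    return FitResult(
        shape=shape,
        expanded=expanded,
        predicted=predicted,
        l2_distance=float(np.sum((predicted.as_array() - freq) ** 2)),
        log_likelihood=log_likelihood(shape, data),
        diagnostics={"closed_form": True},
    )


def fit_per_group_size(
    datasets: dict[int, ObservedCounts],
    kind: str = "linear",
    config: FitConfig | None = None,
) -> dict[int, FitResult | None]:
    """Independent shape fits, one per group size.

    Group size 1 reduces to a Bernoulli model with the exact closed form
    ``r_0 = c_1/N`` (least squares and maximum likelihood coincide there).
    A failing fit is recorded as ``None`` rather than aborting the study.
    """
    results: dict[int, FitResult | None] = {}
    for size in sorted(datasets):
        data = datasets[size]
        if data.n != size:
            raise ValidationError(f"dataset keyed {size} has group size {data.n}")
        try:
            results[size] = _bernoulli_fit(data, kind) if size == 1 else l2_fit(data, kind, config)
        except Exception:
            results[size] = None
    return results


def trend_test(group_sizes, values) -> tuple[float, float]:
    """Pearson correlation of a per-size statistic against group size.

    Returns (ρ, two-sided p) with the p-value from the t distribution with
    ``len − 2`` degrees of freedom.
    """
    x = np.asarray(group_sizes, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need at least 3 paired points for a trend test")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one series; correlation undefined")
    rho, p = scipy.stats.pearsonr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class TrendResult:
    """Per-size linear-fit summaries and their correlations with group size."""

    group_sizes: tuple[int, ...]
    slopes: tuple[float, ...]
    intercepts: tuple[float, ...]
    r0_agnostic: tuple[float, ...]
    slope_trend: tuple[float, float]
    intercept_trend: tuple[float, float]
    r0_trend: tuple[float, float]
    fits: dict = field(compare=False, repr=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "group_size": self.group_sizes,
                "slope": self.slopes,
                "intercept": self.intercepts,
                "r0_agnostic": self.r0_agnostic,
            }
        )

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "group_sizes": list(self.group_sizes),
                "slopes": list(self.slopes),
                "intercepts": list(self.intercepts),
                "r0_agnostic": list(self.r0_agnostic),
                "pearson": {
                    "slope": {"rho": self.slope_trend[0], "p": self.slope_trend[1]},
                    "intercept": {"rho": self.intercept_trend[0], "p": self.intercept_trend[1]},
                    "r0": {"rho": self.r0_trend[0], "p": self.r0_trend[1]},
                },
            }
        )


def analyse_trends(
    datasets: dict[int, ObservedCounts], config: FitConfig | None = None
) -> TrendResult:
    """Full group-size analysis: per-size fits plus the three Pearson tests.

    Slopes and intercepts come from the linear model; the ``r_0`` series
    comes from the shape-free fit, whose first parameter is pinned down by
    the well-sampled frequency of zero-sting trials.
    """
    linear = fit_per_group_size(datasets, "linear", config)
    agnostic = fit_per_group_size(datasets, "agnostic", config)
    sizes = [s for s in sorted(datasets) if linear[s] is not None and agnostic[s] is not None]
    if len(sizes) < 3:
        raise ValidationError("need at least 3 successfully fitted group sizes")
    slopes = tuple(linear[s].shape.theta[1] if s > 1 else 0.0 for s in sizes)
    intercepts = tuple(linear[s].shape.theta[0] for s in sizes)
    r0s = tuple(agnostic[s].shape.theta[0] for s in sizes)
    # group size 1 has no pheromone step, hence no slope information; it is
    # excluded from the slope series but kept for intercepts and r_0
    slope_sizes = [s for s in sizes if s > 1]
    slope_vals = [linear[s].shape.theta[1] for s in slope_sizes]
    return TrendResult(
        group_sizes=tuple(sizes),
        slopes=slopes,
        intercepts=intercepts,
        r0_agnostic=r0s,
        slope_trend=trend_test(slope_sizes, slope_vals),
        intercept_trend=trend_test(sizes, intercepts),
        r0_trend=trend_test(sizes, r0s),
        fits={"linear": linear, "agnostic": agnostic},
    )
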