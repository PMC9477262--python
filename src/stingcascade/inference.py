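"""Parameter inference from end-point sting counts.

The data are repeated i.i.d. trials whose only record is the final sting
count, summarised as a frequency table ``c_0..c_n`` over the ``n + 1``
outcome classes.  Because the cascade's terminal distribution is available
in closed form (:mod:`stingcascade.cascade`), the multinomial likelihood of
such a table is exact — no simulation-based approximation is involved.

Two fitting routes are provided and kept deliberately distinct:

* :func:`l2_fit` — multi-start bounded minimisation of the squared distance
  between predicted outcome probabilities and observed frequencies (the
  point-estimation route; for multinomial data it selects essentially the
  same optima as maximum likelihood),
* :func:`metropolis_hastings` — a random-walk Metropolis sampler targeting
  the exact multinomial likelihood under a uniform prior over the feasible
  region (the uncertainty-quantification route).

:func:`local_sensitivity` scores how strongly the L2 objective reacts to
perturbing each parameter; parameters that only enter through rare outcomes
(high sting counts) score low, which is the signature of high estimation
uncertainty.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .cascade import OutcomeDistribution, ParameterVector, _absorption
from .exceptions import FeasibilityError, FitError, ValidationError
from .shapes import (
    DEFAULT_KM_BOUNDS,
    DEFAULT_NH_BOUNDS,
    ShapeSpec,
    degrees_of_freedom,
    expand,
)

__all__ = [
    "ObservedCounts",
    "FitConfig",
    "FitResult",
    "MCMCTrace",
    "SensitivityResult",
    "l2_fit",
    "log_likelihood",
    "metropolis_hastings",
    "local_sensitivity",
]


@dataclass(frozen=True)
class ObservedCounts:
    """End-point frequency table for one group size.

    ``counts[k]`` is the number of trials that ended with exactly ``k``
    stingers, for ``k = 0..n``.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) < 2:
            raise ValidationError("counts must cover outcomes 0..n with n >= 1")
        if any(c < 0 for c in counts):
            raise ValidationError("trial counts must be non-negative")
        if sum(counts) < 1:
            raise ValidationError("at least one trial is required")

    @property
    def n(self) -> int:
        """Group size."""
        return len(self.counts) - 1

    @property
    def total(self) -> int:
        """Total number of trials N."""
        return sum(self.counts)

    def frequencies(self) -> np.ndarray:
        """Observed relative frequencies ``c_k / N``."""
        return np.asarray(self.counts) / self.total


# ---------------------------------------------------------------------------
# parameterisation of the feasible region for the optimiser
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`l2_fit`."""

    restarts: int = 10
    seed: int = 0
    km_bounds: tuple[float, float] = DEFAULT_KM_BOUNDS
    nh_bounds: tuple[float, float] = DEFAULT_NH_BOUNDS
    maxiter: int = 500


def _box_dim(kind: str, n: int) -> int:
    return degrees_of_freedom(kind, n)


def _box_to_theta(kind: str, x: np.ndarray, n: int, cfg: FitConfig) -> tuple[float, ...]:
    """Map the optimiser's unit/box coordinates onto a feasible θ.

    The monotone agnostic vector is reparameterised as a basal probability
    plus fractional non-negative increments, which maps the unit cube onto
    exactly the feasible region; the linear increment is likewise scaled so
    the top level never exceeds 1.  Hill scale parameters live on a log grid
    inside their configured bounds.
    """
    if kind == "agnostic":
        r = np.empty(n)
        acc = 0.0
        for k in range(n):
            acc = acc + x[k] * (1.0 - acc)
            r[k] = acc
        return tuple(r)
    if kind == "linear":
        r0 = x[0]
        delta = x[1] * (1.0 - r0) / (n - 1) if n > 1 else 0.0
        return (r0, delta)
    r0 = x[0]
    vmax = r0 + x[1] * (1.0 - r0)
    km = math.exp(x[2])
    nh = math.exp(x[3])
    return (r0, vmax, km, nh)


def _box_bounds(kind: str, n: int, cfg: FitConfig) -> list[tuple[float, float]]:
    d = _box_dim(kind, n)
    if kind == "sigmoidal":
        return [
            (0.0, 1.0),
            (0.0, 1.0),
            (math.log(cfg.km_bounds[0]), math.log(cfg.km_bounds[1])),
            (math.log(cfg.nh_bounds[0]), math.log(cfg.nh_bounds[1])),
        ]
    return [(0.0, 1.0)] * d


def _draw_start(kind: str, n: int, cfg: FitConfig, rng: np.random.Generator) -> np.ndarray:
    bounds = _box_bounds(kind, n, cfg)
    return np.array([rng.uniform(lo, hi) for lo, hi in bounds])


def _feasible(kind: str, theta: Sequence[float], n: int) -> bool:
    """Fast feasibility predicate (no exceptions; used inside the sampler loop)."""
    t = np.asarray(theta, dtype=float)
    if kind == "agnostic":
        if len(t) != n or t[0] < 0.0 or t[-1] > 1.0:
            return False
        return bool(np.all(np.diff(t) >= 0.0))
    if kind == "linear":
        r0, delta = t
        return r0 >= 0.0 and delta >= 0.0 and r0 + (n - 1) * delta <= 1.0
    r0, vmax, km, nh = t
    return 0.0 <= r0 <= vmax <= 1.0 and km > 0.0 and nh > 0.0


def _predicted(kind: str, theta: Sequence[float], n: int) -> np.ndarray:
    return _absorption(expand(ShapeSpec(kind, tuple(theta)), n).r)


# ---------------------------------------------------------------------------
# point estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares shape fit."""

    shape: ShapeSpec
    expanded: ParameterVector
    predicted: OutcomeDistribution
    l2_distance: float
    log_likelihood: float
    diagnostics: dict = field(compare=False)


def l2_fit(data: ObservedCounts, kind: str, config: FitConfig | None = None) -> FitResult:
    """Fit shape parameters by minimising Σ_k (f_k(θ) − c_k/N)².

    Multi-start bounded local optimisation (L-BFGS-B) over a reparameterised
    feasible box; the best of all converged starts is returned together with
    per-start diagnostics.
    """
    cfg = config or FitConfig()
    n = data.n
    freq = data.frequencies()

    def objective(x: np.ndarray) -> float:
        theta = _box_to_theta(kind, x, n, cfg)
        pred = _predicted(kind, theta, n)
        return float(np.sum((pred - freq) ** 2))

    rng = np.random.default_rng(cfg.seed)
    bounds = _box_bounds(kind, n, cfg)
    best = None
    per_start = []
    for i in range(cfg.restarts):
        x0 = _draw_start(kind, n, cfg, rng)
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": cfg.maxiter},
        )
        per_start.append(
            {"start": i, "objective": float(res.fun), "converged": bool(res.success)}
        )
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"all {cfg.restarts} optimisation starts failed: {per_start}")

    theta = _box_to_theta(kind, best.x, n, cfg)
    shape = ShapeSpec(kind, theta)
    expanded = expand(shape, n)
    predicted = OutcomeDistribution(tuple(_absorption(expanded.r)))
    return FitResult(
        shape=shape,
        expanded=expanded,
        predicted=predicted,
        l2_distance=float(best.fun),
        log_likelihood=log_likelihood(shape, data),
        diagnostics={
            "restarts": cfg.restarts,
            "seed": cfg.seed,
            "per_start": per_start,
            "n_converged": sum(s["converged"] for s in per_start),
        },
    )


# ---------------------------------------------------------------------------
# exact likelihood and sampling
# ---------------------------------------------------------------------------


def log_likelihood(theta: ShapeSpec | ParameterVector, data: ObservedCounts) -> float:
    """Exact multinomial log-likelihood Σ_k c_k log f_k(θ).

    Outcome classes with zero observed count contribute nothing, even where
    the model assigns them probability zero.  Infeasible θ returns ``-inf``
    (a zero-prior convention, so the sampler can treat feasibility and
    likelihood uniformly) rather than raising.
    """
    if isinstance(theta, ParameterVector):
        theta = ShapeSpec("agnostic", theta.r)
    try:
        params = expand(theta, data.n)
    except (FeasibilityError, ValidationError):
        return -math.inf
    p = _absorption(params.r)
    ll = 0.0
    for c, pk in zip(data.counts, p):
        if c == 0:
            continue
        if pk <= 0.0:
            return -math.inf
        ll += c * math.log(pk)
    return ll


@dataclass(frozen=True)
class MCMCTrace:
    """Full record of one Metropolis-Hastings run.

    ``chain[t]`` is the state after iteration ``t`` (repeats included, as the
    posterior requires); ``accepted[t]`` flags whether the proposal at ``t``
    was taken.
    """

    kind: str
    n: int
    chain: np.ndarray
    log_liks: np.ndarray
    accepted: np.ndarray
    theta_init: tuple[float, ...]
    proposal_scale: tuple[float, ...]
    burn_in: float
    seed: int | None
    iterations: int

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    @property
    def accepted_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(iteration indices, θ values) of the accepted proposals."""
        idx = np.flatnonzero(self.accepted)
        return idx, self.chain[idx]

    def posterior(self) -> np.ndarray:
        """Post-burn-in chain states (the posterior sample, repeats included)."""
        start = int(self.burn_in * self.iterations)
        return self.chain[start:]

    def posterior_mean(self) -> np.ndarray:
        return self.posterior().mean(axis=0)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Equal-tailed marginal credible intervals, shape (d, 2)."""
        tail = 100.0 * (1.0 - level) / 2.0
        post = self.posterior()
        return np.stack(
            [np.percentile(post, tail, axis=0), np.percentile(post, 100.0 - tail, axis=0)],
            axis=1,
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            d = self.chain.shape[1]
            writer.writerow(["iteration"] + [f"theta_{i}" for i in range(d)]
                            + ["log_likelihood", "accepted"])
            for t in range(self.iterations):
                writer.writerow(
                    [t, *(format(float(v), ".17g") for v in self.chain[t]),
                     format(float(self.log_liks[t]), ".17g"), int(self.accepted[t])]
                )

    def summary(self, level: float = 0.95) -> dict:
        ci = self.credible_interval(level)
        return {
            "kind": self.kind,
            "n": self.n,
            "iterations": self.iterations,
            "acceptance_rate": self.acceptance_rate,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "posterior_mean": self.posterior_mean().tolist(),
            "credible_level": level,
            "credible_intervals": ci.tolist(),
        }

    def summary_json(self, level: float = 0.95) -> str:
        return json.dumps(self.summary(level))


def metropolis_hastings(
    data: ObservedCounts,
    kind: str,
    iterations: int,
    theta_init: Sequence[float] | ShapeSpec,
    proposal_scale: float | Sequence[float] = 0.05,
    burn_in: float = 0.25,
    seed: int | None = None,
) -> MCMCTrace:
    """Random-walk Metropolis with the exact multinomial likelihood.

    Proposals perturb every coordinate with an independent Gaussian of the
    given scale; the acceptance probability is ``min(1, L(θ′)/L(θ))``.
    Infeasible proposals (out of bounds, or a non-monotone agnostic vector)
    have zero prior mass and are rejected outright.  The default burn-in
    fraction of 0.25 is discarded by the posterior summaries only — the full
    chain is always recorded.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if not (0.0 <= burn_in < 1.0):
        raise ValidationError("burn_in must be a fraction in [0, 1)")
    n = data.n
    if isinstance(theta_init, ShapeSpec):
        if theta_init.kind != kind:
            raise ValidationError(
                f"theta_init has kind {theta_init.kind!r}, sampler was asked for {kind!r}"
            )
        theta_init = theta_init.theta
    theta = np.asarray(theta_init, dtype=float)
    d = degrees_of_freedom(kind, n)
    if theta.shape != (d,):
        raise ValidationError(f"theta_init must have {d} coordinates for kind {kind!r}")
    if not _feasible(kind, theta, n):
        raise FeasibilityError(f"theta_init {tuple(theta)} is infeasible for n={n}")
    ll = log_likelihood(ShapeSpec(kind, tuple(theta)), data)
    if not math.isfinite(ll):
        raise FitError(
            "theta_init has zero likelihood for the observed counts; "
            "start the sampler from a point with positive likelihood"
        )
    scale = np.broadcast_to(np.asarray(proposal_scale, dtype=float), (d,)).copy()
    if np.any(scale <= 0):
        raise ValidationError("proposal scales must be positive")

    rng = np.random.default_rng(seed)
    chain = np.empty((iterations, d))
    log_liks = np.empty(iterations)
    accepted = np.zeros(iterations, dtype=bool)
    freq_counts = np.asarray(data.counts)
    nz = np.flatnonzero(freq_counts)
    nz_counts = freq_counts[nz]

    def loglik(t: np.ndarray) -> float:
        p = _absorption(expand(ShapeSpec(kind, tuple(t)), n).r)[nz]
        if np.any(p <= 0.0):
            return -math.inf
        return float(np.dot(nz_counts, np.log(p)))

    for t in range(iterations):
        prop = theta + scale * rng.standard_normal(d)
        if _feasible(kind, prop, n):
            ll_prop = loglik(prop)
            if ll_prop >= ll or math.log(rng.uniform()) < ll_prop - ll:
                theta, ll = prop, ll_prop
                accepted[t] = True
        chain[t] = theta
        log_liks[t] = ll

    return MCMCTrace(
        kind=kind,
        n=n,
        chain=chain,
        log_liks=log_liks,
        accepted=accepted,
        theta_init=tuple(float(v) for v in np.asarray(theta_init, dtype=float)),
        proposal_scale=tuple(scale),
        burn_in=burn_in,
        seed=seed,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# local sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityResult:
    """Per-parameter sensitivity of the L2 objective around a point."""

    scores: np.ndarray
    skipped: np.ndarray
    scale: float
    samples: int

    def normalised(self) -> np.ndarray:
        """Scores rescaled to mean 1 (degenerate all-zero scores left as-is)."""
        mean = self.scores.mean()
        if mean <= 0:
            return self.scores.copy()
        return self.scores / mean


def local_sensitivity(
    point: ShapeSpec | ParameterVector,
    data: ObservedCounts,
    scale: float = 0.05,
    samples: int = 100,
    seed: int | None = 0,
) -> SensitivityResult:
    """Sampling-based local sensitivity of the L2 objective.

    Each parameter in turn is perturbed by uniform draws in ``±scale`` while
    the others stay fixed; the score is the mean absolute change of the
    objective per unit perturbation.  Perturbations that leave the feasible
    region are skipped and counted.  A parameter whose feasible neighbourhood
    is empty in both directions (an exact tie in a monotone vector) scores 0.
    """
    if isinstance(point, ParameterVector):
        point = ShapeSpec("agnostic", point.r)
    n = data.n
    point.validate(n)
    theta = np.asarray(point.theta, dtype=float)
    d = len(theta)
    freq = data.frequencies()

    def objective(t: np.ndarray) -> float:
        pred = _absorption(expand(ShapeSpec(point.kind, tuple(t)), n).r)
        return float(np.sum((pred - freq) ** 2))

    base = objective(theta)
    rng = np.random.default_rng(seed)
    scores = np.zeros(d)
    skipped = np.zeros(d, dtype=int)
    if scale == 0.0:
        return SensitivityResult(scores=scores, skipped=skipped, scale=scale, samples=samples)
    for i in range(d):
        deltas = rng.uniform(-scale, scale, samples)
        vals = []
        for delta in deltas:
            if delta == 0.0:
                continue
            pert = theta.copy()
            pert[i] += delta
            if not _feasible(point.kind, pert, n):
                skipped[i] += 1
                continue
            vals.append(abs(objective(pert) - base) / abs(delta))
        scores[i] = float(np.mean(vals)) if vals else 0.0
    return SensitivityResult(scores=scores, skipped=skipped, scale=scale, samples=samples)
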