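"""Exact analysis of the collective stinging cascade.

A group of ``n`` bees faces a threatening stimulus.  Each sting releases one
unit of sting alarm pheromone (SAP), and ``r_k`` denotes the probability that
an individual bee stings once ``k`` stings have already occurred (pheromone
level ``k``).  Because the pheromone only ever raises aggressiveness, the
``r_k`` are non-decreasing in ``k``.  The cascade proceeds in discrete steps:
every bee still available stings independently at the current level, newly
placed stings raise the level, and the process absorbs as soon as a step
produces no new sting (or every bee has stung).  The observable of an
experiment is the final sting count ``K(∞) ∈ {0..n}``.

This module computes the distribution of ``K(∞)`` four independent ways:

* :func:`outcome_distribution` — an exact O(n²)-state dynamic programme,
* :func:`terminal_polynomials` — the same distribution as exact-rational
  polynomials ``f_k(r_0..r_{n-1})``, one per terminal outcome class,
* :func:`brute_force_distribution` — enumeration over aggressiveness
  categories (the test oracle),
* :func:`simulate_cascade` — stochastic realisation of single trials.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
import sympy as sp

from .exceptions import EnumerationCapError, ValidationError

__all__ = [
    "ParameterVector",
    "OutcomeDistribution",
    "CategoryAssignment",
    "TerminalPolynomialSet",
    "CascadeRealisation",
    "outcome_distribution",
    "brute_force_distribution",
    "least_fixed_point",
    "terminal_polynomials",
    "simulate_cascade",
]

_MONOTONE_TOL = 1e-12


@dataclass(frozen=True)
class ParameterVector:
    """Per-level sting probabilities ``r_0 ≤ r_1 ≤ … ≤ r_{n-1}`` for one group size.

    ``r_k`` is the marginal probability that a bee stings when the pheromone
    level (number of prior stings) is ``k``.  The latent aggressiveness
    distribution and thresholds behind these probabilities are identifiable
    only through ``r`` and are deliberately not represented.
    """

    r: tuple[float, ...]

    def __post_init__(self) -> None:
        r = tuple(float(v) for v in self.r)
        object.__setattr__(self, "r", r)
        if len(r) < 1:
            raise ValidationError("parameter vector must have length >= 1")
        for k, v in enumerate(r):
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValidationError(f"r_{k}={v!r} outside [0, 1]")
            if k > 0 and v < r[k - 1] - _MONOTONE_TOL:
                raise ValidationError(
                    f"sting probabilities must be non-decreasing: r_{k}={v} < r_{k-1}={r[k-1]}"
                )

    @property
    def n(self) -> int:
        """Group size."""
        return len(self.r)

    def band_probabilities(self) -> np.ndarray:
        """Probability that a bee falls in each aggressiveness category.

        Category ``j < n`` stings as soon as the pheromone level reaches ``j``;
        the last entry is the never-stinging category.  Bands are
        ``q_0 = r_0``, ``q_j = r_j − r_{j−1}`` and ``q_never = 1 − r_{n−1}``.
        """
        r = np.asarray(self.r)
        q = np.empty(self.n + 1)
        q[0] = r[0]
        q[1:self.n] = np.maximum(r[1:] - r[:-1], 0.0)
        q[self.n] = 1.0 - r[-1]
        return q


@dataclass(frozen=True)
class OutcomeDistribution:
    """Distribution of the final sting count ``K(∞)`` over ``{0..n}``."""

    p: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.p)
        object.__setattr__(self, "p", p)
        if len(p) < 2:
            raise ValidationError("outcome distribution needs at least 2 classes")
        for k, v in enumerate(p):
            if v < -1e-12 or v > 1.0 + 1e-12:
                raise ValidationError(f"p_{k}={v!r} outside [0, 1]")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValidationError(f"probabilities sum to {sum(p)!r}, not 1")

    @property
    def n(self) -> int:
        return len(self.p) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p)

    def mean(self) -> float:
        """Expected final sting count E[K(∞)]."""
        return float(np.dot(np.arange(self.n + 1), self.p))


@dataclass(frozen=True)
class CategoryAssignment:
    """Counts of bees per aggressiveness category for a group of size ``n``.

    ``counts[j]`` for ``j < n`` is the number of bees that sting as soon as
    the pheromone level reaches ``j``; ``counts[n]`` is the number of bees
    that never sting.  The cascade outcome is a deterministic function of
    this assignment (see :func:`least_fixed_point`).
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) < 2:
            raise ValidationError("assignment needs categories 0..n-1 plus never")
        if any(c < 0 for c in counts):
            raise ValidationError("category counts must be non-negative")
        if sum(counts) != len(counts) - 1:
            raise ValidationError(
                f"category counts sum to {sum(counts)}, expected group size {len(counts) - 1}"
            )

    @property
    def n(self) -> int:
        return len(self.counts) - 1


def least_fixed_point(assignment: CategoryAssignment) -> int:
    """Deterministic final sting count of a category assignment.

    Iterates ``k ← g(k)`` from ``k = 0``, where ``g(k)`` counts the bees in
    categories ``0..k``.  Because ``g`` is monotone the iteration reaches the
    least fixed point of ``g``, which is the cascade's terminal count
    regardless of how simultaneous stings interleave.
    """
    cumulative = np.cumsum(assignment.counts[:-1])
    k = 0
    while True:
        g = int(cumulative[min(k, assignment.n - 1)])
        if g == k:
            return k
        k = g


def _absorption(r: tuple[float, ...]) -> np.ndarray:
    """Dynamic programme over states (m remaining, c = level last declined at).

    The current pheromone level in state ``(m, c)`` is ``k = n − m``; each
    remaining bee stings with the conditional probability
    ``(r_k − r_c)/(1 − r_c)`` (``r_⊥ = 0`` for the initial state).  A step
    with zero new stings absorbs at count ``k``.
    """
    n = len(r)
    memo: dict[tuple[int, int], np.ndarray] = {}

    def rec(m: int, c: int) -> np.ndarray:
        key = (m, c)
        hit = memo.get(key)
        if hit is not None:
            return hit
        res = np.zeros(n + 1)
        if m == 0:
            res[n] = 1.0
        else:
            k = n - m
            rc = r[c] if c >= 0 else 0.0
            if rc >= 1.0:
                # unreachable (entered with probability 0); prune by absorbing
                res[k] = 1.0
            else:
                p = (r[k] - rc) / (1.0 - rc)
                p = min(max(p, 0.0), 1.0)
                q = 1.0 - p
                for s in range(m + 1):
                    w = math.comb(m, s) * p**s * q ** (m - s)
                    if w == 0.0:
                        continue
                    if s == 0:
                        res[k] += w
                    else:
                        res += w * rec(m - s, k)
        memo[key] = res
        return res

    return rec(n, -1)


def outcome_distribution(params: ParameterVector) -> OutcomeDistribution:
    """Exact distribution of the final sting count under the cascade."""
    return OutcomeDistribution(tuple(_absorption(params.r)))


def _compositions(total: int, parts: int):
    """Yield all tuples of ``parts`` non-negative ints summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head,) + tail


def brute_force_distribution(params: ParameterVector, cap: int = 8) -> OutcomeDistribution:
    """Oracle: exhaustive enumeration over aggressiveness categories.

    Every bee independently falls into one of ``n + 1`` categories with the
    band probabilities of :meth:`ParameterVector.band_probabilities`; the
    final count of each :class:`CategoryAssignment` is deterministic.  The
    outcome distribution is accumulated over all multinomial assignments.
    Intended for small ``n`` only — this is the independent cross-check for
    :func:`outcome_distribution`, not a production path.
    """
    n = params.n
    if n > cap:
        raise EnumerationCapError(
            f"brute force enumeration requested for n={n} above cap {cap}"
        )
    q = params.band_probabilities()
    fact_n = math.factorial(n)
    p = np.zeros(n + 1)
    for counts in _compositions(n, n + 1):
        prob = 1.0
        for c, qj in zip(counts, q):
            if c:
                if qj == 0.0:
                    prob = 0.0
                    break
                prob *= qj**c
        if prob == 0.0:
            continue
        multinom = fact_n
        for c in counts:
            multinom //= math.factorial(c)
        k = least_fixed_point(CategoryAssignment(counts))
        p[k] += multinom * prob
    return OutcomeDistribution(tuple(p))


# ---------------------------------------------------------------------------
# symbolic terminal polynomials
# ---------------------------------------------------------------------------


def _symbols(n: int) -> tuple[sp.Symbol, ...]:
    return sp.symbols(f"r0:{n}", nonnegative=True)


@lru_cache(maxsize=32)
def _terminal_polys(n: int) -> tuple[sp.Expr, ...]:
    """Fraction-free symbolic recursion.

    With ``D̃(m, c) = (1 − r_c)^m · D(m, c)`` the conditional-probability
    denominators cancel telescopically and every terminal reachability
    function is a genuine polynomial:

        D̃(m, c)[j] = (1 − r_k)^m [j = n−m]
                      + Σ_{s=1..m} C(m, s) (r_k − r_c)^s D̃(m−s, k)[j]

    where ``k = n − m`` and ``r_⊥ = 0``, so ``f_j = D̃(n, ⊥)[j]``.
    """
    r = _symbols(n)
    memo: dict[tuple[int, int], dict[int, sp.Expr]] = {}

    def rec(m: int, c: int) -> dict[int, sp.Expr]:
        key = (m, c)
        if key in memo:
            return memo[key]
        if m == 0:
            res = {n: sp.Integer(1)}
        else:
            k = n - m
            rc = r[c] if c >= 0 else sp.Integer(0)
            res = {k: sp.expand((1 - r[k]) ** m)}
            for s in range(1, m + 1):
                w = sp.binomial(m, s) * (r[k] - rc) ** s
                for j, sub in rec(m - s, k).items():
                    term = sp.expand(w * sub)
                    res[j] = sp.expand(res.get(j, sp.Integer(0)) + term)
        memo[key] = res
        return res

    top = rec(n, -1)
    return tuple(top.get(j, sp.Integer(0)) for j in range(n + 1))


@dataclass(frozen=True)
class TerminalPolynomialSet:
    """Exact-rational polynomials ``f_k(r_0..r_{n-1}) = P(K(∞) = k)``.

    One polynomial per terminal outcome class of the cascade, indexed by the
    final sting count (the observable), not by any tool-internal labelling of
    absorbing components.
    """

    n: int
    polys: tuple[sp.Expr, ...]
    _lambdified: Callable | None = field(default=None, compare=False, repr=False)

    @property
    def variables(self) -> tuple[sp.Symbol, ...]:
        return _symbols(self.n)

    def _func(self) -> Callable:
        if self._lambdified is None:
            f = sp.lambdify(self.variables, list(self.polys), modules="numpy")
            object.__setattr__(self, "_lambdified", f)
        return self._lambdified

    def evaluate(self, params: ParameterVector) -> OutcomeDistribution:
        if params.n != self.n:
            raise ValidationError(
                f"parameter vector has n={params.n}, polynomials have n={self.n}"
            )
        vals = self._func()(*params.r)
        return OutcomeDistribution(tuple(float(v) for v in vals))

    def canonical_strings(self) -> list[str]:
        """Plain-text canonical form: sorted monomials, exact fractions."""
        out = []
        for expr in self.polys:
            poly = sp.Poly(expr, *self.variables, domain="QQ")
            terms = []
            for monom, coeff in sorted(poly.terms(), reverse=True):
                factors = []
                if coeff != 1 or not any(monom):
                    factors.append(str(coeff))
                for sym, power in zip(self.variables, monom):
                    if power == 1:
                        factors.append(str(sym))
                    elif power > 1:
                        factors.append(f"{sym}^{power}")
                terms.append("*".join(factors) if factors else "1")
            out.append(" + ".join(terms) if terms else "0")
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "variables": [str(s) for s in self.variables],
                "polynomials": [sp.srepr(p) for p in self.polys],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TerminalPolynomialSet":
        obj = json.loads(text)
        polys = tuple(sp.sympify(s) for s in obj["polynomials"])
        return cls(n=int(obj["n"]), polys=polys)


def terminal_polynomials(n: int, cap: int = 12) -> TerminalPolynomialSet:
    """Terminal-outcome polynomials for group size ``n`` (symbolic blow-up cap)."""
    if n < 1:
        raise ValidationError("group size must be >= 1")
    if n > cap:
        raise EnumerationCapError(f"symbolic recursion requested for n={n} above cap {cap}")
    return TerminalPolynomialSet(n=n, polys=_terminal_polys(n))


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CascadeRealisation:
    """One stochastic trial: terminal count plus the per-step new-sting trace."""

    final_count: int
    new_stings: tuple[int, ...]

    def observable_trace(self) -> tuple[int, ...]:
        """The pheromone level ``K(t)`` after each step."""
        return tuple(np.cumsum(self.new_stings))


def simulate_cascade(
    params: ParameterVector, seed: int | np.random.Generator | None = None
) -> CascadeRealisation:
    """Simulate a single cascade trial.

    Each step draws the number of new stings among remaining bees from a
    binomial with the conditional recruitment probability; the trial ends at
    the first step with no new sting.  Identical seeds give identical traces.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n
    r = params.r
    m = n  # remaining bees
    rc = 0.0  # probability level at which remaining bees last declined
    steps: list[int] = []
    while m > 0:
        k = n - m
        p = (r[k] - rc) / (1.0 - rc) if rc < 1.0 else 0.0
        s = int(rng.binomial(m, min(max(p, 0.0), 1.0)))
        if s == 0:
            break
        steps.append(s)
        m -= s
        rc = r[k]
    return CascadeRealisation(final_count=n - m, new_stings=tuple(steps))
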