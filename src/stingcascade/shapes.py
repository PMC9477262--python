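"""Low-dimensional parameterisations of the sting-probability curve.

Three hypotheses about how the per-level sting probability ``r_i`` depends on
the pheromone level ``i``:

* ``agnostic`` — every ``r_i`` is a free parameter under the monotonicity
  constraint only (``n`` parameters),
* ``linear`` — ``r_i = r_0 + i·Δ`` (2 parameters),
* ``sigmoidal`` — a Hill saturation curve
  ``r_i = r_0 + (V_max − r_0)/(1 + (K_m/i)^{n_H})`` for ``i ≥ 1`` and exactly
  ``r_0`` at level 0 (4 parameters: basal level ``r_0``, saturation level
  ``V_max``, half-slope point ``K_m`` in pheromone units, Hill coefficient
  ``n_H``).

Infeasible parameter tuples are rejected, never clipped: clipping would make
distinct θ map to the same likelihood and break both the optimiser's
diagnostics and the propriety of the sampler's uniform prior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .cascade import ParameterVector
from .exceptions import FeasibilityError, ValidationError

__all__ = ["ShapeSpec", "expand", "degrees_of_freedom", "SHAPE_KINDS"]

SHAPE_KINDS = ("agnostic", "linear", "sigmoidal")

#: Widest feasible default boxes for the Hill curve's scale parameters.
#: The half-slope point is measured in pheromone units (stings), so values far
#: beyond the largest group size carry no information; the Hill coefficient is
#: capped where the curve is numerically a step.
DEFAULT_KM_BOUNDS = (1e-3, 50.0)
DEFAULT_NH_BOUNDS = (1e-2, 10.0)


@dataclass(frozen=True)
class ShapeSpec:
    """A shape kind plus its parameter tuple θ and admissible bounds."""

    kind: str
    theta: tuple[float, ...]
    bounds: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValidationError(f"unknown shape kind {self.kind!r}; expected one of {SHAPE_KINDS}")
        theta = tuple(float(v) for v in self.theta)
        object.__setattr__(self, "theta", theta)
        if self.bounds is not None:
            bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
            if len(bounds) != len(theta):
                raise ValidationError("bounds must match theta length")
            object.__setattr__(self, "bounds", bounds)
        if self.kind == "linear" and len(theta) != 2:
            raise ValidationError("linear shape takes theta = (r_0, delta)")
        if self.kind == "sigmoidal" and len(theta) != 4:
            raise ValidationError("sigmoidal shape takes theta = (r_0, v_max, k_m, n_hill)")

    def validate(self, n: int) -> None:
        """Raise :class:`FeasibilityError` if θ is infeasible for group size ``n``."""
        t = self.theta
        if self.kind == "agnostic":
            if len(t) != n:
                raise FeasibilityError(f"agnostic theta has length {len(t)}, group size is {n}")
            try:
                ParameterVector(t)
            except ValidationError as exc:
                raise FeasibilityError(str(exc)) from exc
        elif self.kind == "linear":
            r0, delta = t
            if r0 < 0:
                raise FeasibilityError(f"basal probability r_0={r0} < 0")
            if delta < 0:
                raise FeasibilityError(f"increment delta={delta} < 0")
            if r0 + (n - 1) * delta > 1.0 + 1e-12:
                raise FeasibilityError(
                    f"top level r_0 + (n-1)*delta = {r0 + (n - 1) * delta} exceeds 1"
                )
        else:
            r0, vmax, km, nh = t
            if not (0.0 <= r0 <= vmax <= 1.0):
                raise FeasibilityError(
                    f"need 0 <= r_0 <= v_max <= 1, got r_0={r0}, v_max={vmax}"
                )
            if km <= 0:
                raise FeasibilityError(f"half-slope point k_m={km} must be positive")
            if nh <= 0:
                raise FeasibilityError(f"Hill coefficient n_hill={nh} must be positive")
        if self.bounds is not None:
            for i, (v, (lo, hi)) in enumerate(zip(t, self.bounds)):
                if not (lo <= v <= hi):
                    raise FeasibilityError(f"theta[{i}]={v} outside bound [{lo}, {hi}]")

    def is_feasible(self, n: int) -> bool:
        try:
            self.validate(n)
        except FeasibilityError:
            return False
        return True

    # -- serialisation ------------------------------------------------------

    _PARAM_NAMES = {
        "linear": ("r0", "delta"),
        "sigmoidal": ("r0", "v_max", "k_m", "n_hill"),
    }

    def to_json(self) -> str:
        if self.kind == "agnostic":
            params: dict = {"r": list(self.theta)}
        else:
            params = dict(zip(self._PARAM_NAMES[self.kind], self.theta))
        obj = {"kind": self.kind, "parameters": params}
        if self.bounds is not None:
            obj["bounds"] = [list(b) for b in self.bounds]
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "ShapeSpec":
        obj = json.loads(text)
        kind = obj["kind"]
        params = obj["parameters"]
        if kind == "agnostic":
            theta = tuple(params["r"])
        else:
            theta = tuple(params[name] for name in cls._PARAM_NAMES[kind])
        bounds = tuple(tuple(b) for b in obj["bounds"]) if "bounds" in obj else None
        return cls(kind=kind, theta=theta, bounds=bounds)


def hill(i: float, r0: float, vmax: float, km: float, nh: float) -> float:
    """Hill dose-response value at pheromone level ``i ≥ 1``."""
    return r0 + (vmax - r0) / (1.0 + (km / i) ** nh)


def expand(shape: ShapeSpec, n: int) -> ParameterVector:
    """Map a shape specification to the full per-level probability vector."""
    if n < 1:
        raise ValidationError("group size must be >= 1")
    shape.validate(n)
    t = shape.theta
    if shape.kind == "agnostic":
        return ParameterVector(t)
    if shape.kind == "linear":
        r0, delta = t
        return ParameterVector(tuple(min(r0 + i * delta, 1.0) for i in range(n)))
    r0, vmax, km, nh = t
    # level 0 carries no pheromone: the Hill term is defined for i >= 1 only
    # and the basal probability applies exactly.
    r = [r0] + [hill(i, r0, vmax, km, nh) for i in range(1, n)]
    return ParameterVector(tuple(min(max(v, 0.0), 1.0) for v in r))


def degrees_of_freedom(kind: str, n: int) -> int:
    """Number of free parameters of a shape kind at group size ``n``."""
    if kind == "agnostic":
        return n
    if kind == "linear":
        return 2
    if kind == "sigmoidal":
        return 4
    raise ValidationError(f"unknown shape kind {kind!r}")
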