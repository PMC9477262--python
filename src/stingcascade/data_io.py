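"""Reading and writing end-point count tables, plus binomial confidence intervals.

The single canonical on-disk format is a CSV with header
``group_size,k,count``: one row per (group size, outcome class) pair, with
``k`` running contiguously from 0 to the group size.  The bundled fixture
``fig2_group10.csv`` is the published frequency table for groups of 10 bees
(92 trials).

Per-category uncertainty on observed outcome frequencies is summarised with
Agresti-Coull adjusted-Wald intervals, optionally Bonferroni-corrected
(Dunn's correction) for the ``m`` simultaneous intervals of one frequency
plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError
from .inference import ObservedCounts

__all__ = [
    "ConfidenceInterval",
    "load_counts",
    "save_counts",
    "agresti_coull_ci",
    "category_intervals",
    "fig2_counts",
]

_COLUMNS = ["group_size", "k", "count"]


def load_counts(path) -> dict[int, ObservedCounts]:
    """Load a count table, keyed by group size.

    Outcome classes missing from the file are treated as zero-count rows;
    duplicated or out-of-range classes are rejected with the offending rows
    named.
    """
    frame = pd.read_csv(path)
    if list(frame.columns) != _COLUMNS:
        raise ValidationError(
            f"{path}: expected header {','.join(_COLUMNS)}, found {','.join(map(str, frame.columns))}"
        )
    if frame.empty:
        raise ValidationError(f"{path}: no data rows")
    out: dict[int, ObservedCounts] = {}
    for size, group in frame.groupby("group_size", sort=True):
        size = int(size)
        if size < 1:
            raise ValidationError(f"{path}: group_size {size} must be >= 1")
        counts = [0] * (size + 1)
        seen: set[int] = set()
        for k, c in zip(group["k"], group["count"]):
            k, c = int(k), int(c)
            if not (0 <= k <= size):
                raise ValidationError(
                    f"{path}: outcome class k={k} out of range for group_size={size}"
                )
            if k in seen:
                raise ValidationError(f"{path}: duplicate row for group_size={size}, k={k}")
            if c < 0:
                raise ValidationError(f"{path}: negative count for group_size={size}, k={k}")
            seen.add(k)
            counts[k] = c
        out[size] = ObservedCounts(tuple(counts))
    return out


def save_counts(datasets: dict[int, ObservedCounts] | ObservedCounts, path) -> None:
    """Write count tables in the canonical CSV dialect."""
    if isinstance(datasets, ObservedCounts):
        datasets = {datasets.n: datasets}
    rows = [
        {"group_size": size, "k": k, "count": c}
        for size in sorted(datasets)
        for k, c in enumerate(datasets[size].counts)
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def fig2_counts() -> ObservedCounts:
    """The bundled published frequency table for groups of 10 bees (N = 92)."""
    ref = resources.files("stingcascade").joinpath("data/fig2_group10.csv")
    with resources.as_file(ref) as path:
        return load_counts(Path(path))[10]


@dataclass(frozen=True)
class ConfidenceInterval:
    """An Agresti-Coull interval for one binomial proportion."""

    point: float
    lower: float
    upper: float
    level: float
    m: int

    @property
    def standard_error(self) -> float:
        """The adjusted standard error √(p̃(1−p̃)/ñ) behind the interval."""
        z = _z_value(self.level, self.m)
        return (self.upper - self.lower) / (2.0 * z) if z > 0 else 0.0


def _z_value(level: float, m: int) -> float:
    alpha = (1.0 - level) / m
    return float(norm.ppf(1.0 - alpha / 2.0))


def agresti_coull_ci(
    successes: int, trials: int, level: float = 0.90, m: int = 1
) -> ConfidenceInterval:
    """Agresti-Coull interval with optional Dunn (Bonferroni) correction.

    The per-interval error budget is ``α′ = α/m`` for ``m`` simultaneous
    intervals; with ``z`` the normal quantile at ``1 − α′/2`` the adjusted
    counts are ``ñ = trials + z²`` and ``p̃ = (successes + z²/2)/ñ``, giving
    ``p̃ ± z √(p̃(1 − p̃)/ñ)`` truncated to [0, 1].
    """
    if trials < 1:
        raise ValidationError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ValidationError(f"successes={successes} outside [0, {trials}]")
    if not (0.0 < level < 1.0):
        raise ValidationError("confidence level must be in (0, 1)")
    if m < 1:
        raise ValidationError("number of simultaneous intervals m must be >= 1")
    z = _z_value(level, m)
    n_tilde = trials + z * z
    p_tilde = (successes + z * z / 2.0) / n_tilde
    half = z * math.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return ConfidenceInterval(
        point=successes / trials,
        lower=max(0.0, p_tilde - half),
        upper=min(1.0, p_tilde + half),
        level=level,
        m=m,
    )


def category_intervals(
    data: ObservedCounts, level: float = 0.90, dunn: bool = True
) -> list[ConfidenceInterval]:
    """Simultaneous per-outcome-class intervals for one frequency table.

    With ``dunn=True`` the Bonferroni budget is split over the ``n + 1``
    outcome classes shown together in a frequency plot.
    """
    m = data.n + 1 if dunn else 1
    return [agresti_coull_ci(c, data.total, level=level, m=m) for c in data.counts]


def category_standard_errors(data: ObservedCounts, level: float = 0.90, dunn: bool = True):
    """Adjusted standard errors √(p̃(1−p̃)/ñ) per outcome class."""
    import numpy as np

    m = data.n + 1 if dunn else 1
    z = _z_value(level, m)
    n_tilde = data.total + z * z
    p_tilde = (np.asarray(data.counts) + z * z / 2.0) / n_tilde
    return np.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
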