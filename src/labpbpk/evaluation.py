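"""Model-qualification statistics.

Observed/predicted fold ratios, the average fold error (geometric mean of
ratios), the inclusive two-fold acceptance criterion, per-timepoint
percentile bands for visual predictive checks, and bootstrap box-plot
summaries (median with 95% CI) for severity comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nca import ConcentrationProfile

TWO_FOLD_RANGE = (0.5, 2.0)  # inclusive at both ends
DEFAULT_BOOTSTRAP_RESAMPLES = 10_000


@dataclass(frozen=True)
class ObsPredPair:
    """One observed/predicted PK-parameter comparison."""

    parameter: str  # "cmax" | "auc_0_t" | "cl"
    observed: float
    predicted: float
    study_id: int | str = ""
    route: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        if self.observed <= 0 or self.predicted <= 0:
            raise ValueError("observed and predicted must be positive")


def fold_ratio(pair: ObsPredPair) -> float:
    """Observed divided by predicted."""
    return pair.observed / pair.predicted


def afe(ratios: Sequence[float]) -> float:
    """Average fold error: 10^(mean log10 ratio), i.e. the geometric mean."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("afe requires at least one ratio")
    if np.any(ratios <= 0):
        raise ValueError("all ratios must be positive")
    return float(10.0 ** np.mean(np.log10(ratios)))


def two_fold_flags(ratios: Sequence[float]) -> list[bool]:
    """True where the ratio lies inside the inclusive [0.5, 2.0] range."""
    lo, hi = TWO_FOLD_RANGE
    flags = []
    for r in ratios:
        if r <= 0:
            raise ValueError(f"ratio must be positive, got {r}")
        flags.append(lo <= r <= hi)
    return flags


@dataclass(frozen=True)
class EvalReport:
    """Ratios, per-group AFE, and two-fold flags for a set of pairs."""

    pairs: tuple[ObsPredPair, ...]
    ratios: tuple[float, ...]
    two_fold: tuple[bool, ...]
    afe_by_group: dict  # (route, population, parameter) -> AFE
    ratio_mode: str  # "full_precision" | "rounded_2dp"

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def all_within_two_fold(self) -> bool:
        return all(self.two_fold)


def evaluate_pairs(
    pairs: Sequence[ObsPredPair], ratio_mode: str = "full_precision"
) -> EvalReport:
    """Build an :class:`EvalReport`.

    ``ratio_mode="rounded_2dp"`` rounds each ratio to 2 decimals before AFE
    aggregation, matching how the source tables print ratio columns.
    """
    if ratio_mode not in ("full_precision", "rounded_2dp"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    if not pairs:
        raise ValueError("evaluate_pairs requires at least one pair")
    ratios = [fold_ratio(p) for p in pairs]
    if ratio_mode == "rounded_2dp":
        ratios = [round(r, 2) for r in ratios]
    flags = two_fold_flags(ratios)
    groups: dict[tuple, list[float]] = {}
    for pair, ratio in zip(pairs, ratios):
        groups.setdefault((pair.route, pair.population, pair.parameter), []).append(ratio)
    afe_by_group = {key: afe(values) for key, values in groups.items()}
    return EvalReport(
        pairs=tuple(pairs),
        ratios=tuple(ratios),
        two_fold=tuple(flags),
        afe_by_group=afe_by_group,
        ratio_mode=ratio_mode,
    )


@dataclass(frozen=True)
class BandSummary:
    """Per-timepoint population statistics for a visual predictive check."""

    time: np.ndarray
    mean: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    p5: np.ndarray
    p95: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.time,
                "mean": self.mean,
                "min": self.minimum,
                "max": self.maximum,
                "p5": self.p5,
                "p95": self.p95,
            }
        )


def percentile_bands(profiles: Sequence[ConcentrationProfile]) -> BandSummary:
    """5th/95th percentile, mean, min, max across profiles on a common grid.

    Percentiles use linear interpolation between order statistics
    (numpy's default "linear" method).
    """
    if len(profiles) < 2:
        raise ValueError("percentile bands need at least 2 profiles")
    grid = profiles[0].time
    for p in profiles[1:]:
        if p.time.shape != grid.shape or not np.allclose(p.time, grid):
            raise ValueError("profiles must share an identical time grid")
    values = np.vstack([p.concentration for p in profiles])
    return BandSummary(
        time=grid.copy(),
        mean=values.mean(axis=0),
        minimum=values.min(axis=0),
        maximum=values.max(axis=0),
        p5=np.percentile(values, 5, axis=0, method="linear"),
        p95=np.percentile(values, 95, axis=0, method="linear"),
    )


@dataclass(frozen=True)
class BoxSummary:
    """Median with a bootstrap 95% confidence interval."""

    median: float
    ci_95: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        low, high = self.ci_95
        if low > high:
            raise ValueError("ci_95 low must not exceed high")


def box_summary(
    values: Sequence[float],
    n_boot: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    seed: int = 0,
) -> BoxSummary:
    """Median and seeded percentile-bootstrap 95% CI of the median."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("box_summary needs at least 3 values")
    rng = np.random.default_rng(seed)
    resamples = rng.choice(values, size=(n_boot, values.size), replace=True)
    medians = np.median(resamples, axis=1)
    low, high = np.percentile(medians, [2.5, 97.5])
    return BoxSummary(median=float(np.median(values)), ci_95=(float(low), float(high)),
                      n=int(values.size))
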