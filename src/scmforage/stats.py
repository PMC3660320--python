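"""Latency analytics and decision tests.

Scale-free latency summaries (ECDF-area scores), choice-vs-single
shortening, one-sample preference tests on arcsine-square-root transformed
proportions, paired tests on log medians, and the session-stability rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "EcdfScore",
    "TestResult",
    "StabilityVerdict",
    "arcsine_sqrt",
    "ecdf_score",
    "default_grid",
    "shortening",
    "preference_test",
    "compare_latency_conditions",
    "stability_check",
]


@dataclass
class EcdfScore:
    option: str
    condition: str
    grid: np.ndarray
    score: float  # mean ECDF height over the grid; larger = shorter latencies


@dataclass
class TestResult:
    statistic: float
    df: int
    pvalue: float
    degenerate: bool = False  # zero variance; statistic/pvalue are conventions


@dataclass
class StabilityVerdict:
    last_three: tuple[float, float, float]  # choice percentages
    sd: float
    slope: float  # points per session, least squares
    stable: bool


def arcsine_sqrt(p: float) -> float:
    """Variance-stabilising transform for proportions: arcsin(sqrt(p))."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def default_grid(*latency_sets: Sequence[float], n: int = 9) -> np.ndarray:
    """Shared comparison grid: empirical deciles of the pooled latencies."""
    pooled = np.concatenate([np.asarray(x, dtype=float) for x in latency_sets])
    if pooled.size == 0:
        raise ValueError("no latencies to build a grid from")
    qs = np.arange(1, n + 1) / (n + 1)
    grid = np.quantile(pooled, qs)
    return np.unique(grid)


def ecdf_score(
    latencies: Sequence[float],
    grid: Sequence[float],
    option: str = "",
    condition: str = "",
) -> EcdfScore:
    """Mean empirical-CDF height over the grid points.

    Larger scores mean shorter latencies overall (more of the distribution's
    mass lies below the cut points).
    """
    lat = np.sort(np.asarray(latencies, dtype=float))
    if lat.size == 0:
        raise ValueError("empty latency sample")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    heights = np.searchsorted(lat, grid, side="right") / lat.size
    return EcdfScore(
        option=option, condition=condition, grid=grid, score=float(heights.mean())
    )


def shortening(
    single: Sequence[float],
    choice: Sequence[float],
    grid: Sequence[float] | None = None,
) -> float:
    """ECDF-score difference (choice - single) for one option.

    Positive values mean choice latencies are shorter than single-option
    latencies. If no grid is supplied, the pooled deciles of both samples
    are used so the two conditions are scored on a common scale.
    """
    if grid is None:
        grid = default_grid(single, choice)
    s = ecdf_score(single, grid).score
    c = ecdf_score(choice, grid).score
    return c - s


def _one_sample_t(x: np.ndarray, popmean: float) -> TestResult:
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    diff = x.mean() - popmean
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        if diff == 0:
            return TestResult(0.0, n - 1, 1.0, degenerate=True)
        return TestResult(float(np.sign(diff) * np.inf), n - 1, 0.0, degenerate=True)
    t, p = sps.ttest_1samp(x, popmean)
    return TestResult(float(t), n - 1, float(p))


def preference_test(
    per_subject_proportions: Sequence[float], null: float = 0.5
) -> TestResult:
    """One-sample t of choice proportions against indifference, after
    arcsine-square-root transforming both the data and the null."""
    props = np.asarray(per_subject_proportions, dtype=float)
    x = np.arcsin(np.sqrt(np.clip(props, 0.0, 1.0)))
    if np.any(props < 0) or np.any(props > 1):
        raise ValueError("proportions must lie in [0, 1]")
    return _one_sample_t(x, arcsine_sqrt(null))


def compare_latency_conditions(
    single_medians: Sequence[float], choice_medians: Sequence[float]
) -> TestResult:
    """Paired t on natural-log median latencies (single vs choice),
    one pair per subject."""
    s = np.asarray(single_medians, dtype=float)
    c = np.asarray(choice_medians, dtype=float)
    if s.shape != c.shape:
        raise ValueError("conditions must be paired (equal lengths)")
    if np.any(s <= 0) or np.any(c <= 0):
        raise ValueError("medians must be positive for the log transform")
    return _one_sample_t(np.log(c) - np.log(s), 0.0)


def stability_check(
    choice_pcts: Sequence[float],
    sd_threshold: float = 10.0,
    trend_threshold: float = 5.0,
) -> StabilityVerdict:
    """Stability rule over the last three sessions: SD of the choice
    percentages below ``sd_threshold`` points and absolute least-squares
    slope below ``trend_threshold`` points/session."""
    pcts = np.asarray(choice_pcts, dtype=float)
    if pcts.size < 3:
        raise ValueError("need at least three sessions")
    last = pcts[-3:]
    sd = float(last.std(ddof=1))
    # least-squares slope; exact closed form for three equally spaced sessions
    slope = float((last[2] - last[0]) / 2.0)
    return StabilityVerdict(
        last_three=tuple(last),
        sd=sd,
        slope=slope,
        stable=bool(sd < sd_threshold and abs(slope) < trend_threshold),
    )
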