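"""The race model of simultaneous choice.

In a choice trial each option is processed independently and the option
whose latency process finishes first is taken; there is no comparison
stage. Preference in simultaneous presentations is therefore predictable
from no-choice latencies alone: resample one latency per option from the
single-option samples and count which option wins the race.

Two routes are provided: a Monte Carlo over resampled empirical latencies
(:func:`predict_preference`) and a quadrature oracle over parametric laws
(:func:`analytic_preference`). The winner latencies retained by the Monte
Carlo are the censored minima that predict choice-latency shortening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "LatencySample",
    "PreferencePrediction",
    "CensoredSummary",
    "race_trial",
    "predict_preference",
    "analytic_preference",
    "censored_latency_summary",
]

SINGLE_OPTION = "single_option"
CHOSEN_IN_CHOICE = "chosen_in_choice"


@dataclass
class LatencySample:
    """Labelled latencies (s) for one option under one condition."""

    option: str
    latencies: np.ndarray
    condition: str = SINGLE_OPTION
    subject: str | None = None

    def __post_init__(self) -> None:
        self.latencies = np.asarray(self.latencies, dtype=float)
        if self.latencies.size == 0:
            raise ValueError(f"empty latency sample for option {self.option!r}")
        if np.any(self.latencies <= 0):
            raise ValueError(f"non-positive latencies in sample for {self.option!r}")

    def __len__(self) -> int:
        return int(self.latencies.size)


@dataclass
class PreferencePrediction:
    """Monte Carlo race output for one pairing."""

    pairing: tuple[str, str]
    n_experiments: int
    n_trials: int
    preference: dict[str, float]  # option -> predicted choice proportion
    mc_sd: float  # SD of per-experiment preference for pairing[0]
    mc_se: float  # SE of the mean preference
    winner_latencies: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    per_experiment: np.ndarray = field(repr=False, default=None)


@dataclass
class CensoredSummary:
    option: str
    n_wins: int
    median: float | None
    empty: bool


def race_trial(
    lat_a: float, lat_b: float, rng: np.random.Generator
) -> tuple[int, float]:
    """Resolve one race: returns (winner index 0/1, winning latency).

    Exact ties are broken by a fair coin.
    """
    if lat_a <= 0 or lat_b <= 0:
        raise ValueError(f"latencies must be positive, got ({lat_a}, {lat_b})")
    if lat_a == lat_b:
        return int(rng.integers(2)), float(lat_a)
    return (0, float(lat_a)) if lat_a < lat_b else (1, float(lat_b))


def predict_preference(
    sample_a: LatencySample,
    sample_b: LatencySample,
    n_trials: int = 96,
    n_experiments: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
) -> PreferencePrediction:
    """Race Monte Carlo: ``n_experiments`` simulated experiments of
    ``n_trials`` choice trials, each trial drawing one latency per option
    (with replacement) from the single-option samples and taking the faster.

    Each experiment runs on its own child random stream, so increasing
    ``n_experiments`` extends rather than perturbs the sequence.
    """
    if n_trials <= 0 or n_experiments <= 0:
        raise ValueError("n_trials and n_experiments must be positive")
    a = sample_a.latencies
    b = sample_b.latencies
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    per_experiment = np.empty(n_experiments)
    wins_a: list[np.ndarray] = []
    wins_b: list[np.ndarray] = []
    for e, child in enumerate(root.spawn(n_experiments)):
        rng = np.random.Generator(np.random.PCG64(child))
        la = a[rng.integers(0, a.size, n_trials)]
        lb = b[rng.integers(0, b.size, n_trials)]
        a_wins = la < lb
        ties = la == lb
        if np.any(ties):
            a_wins = a_wins | (ties & (rng.random(n_trials) < 0.5))
        per_experiment[e] = a_wins.mean()
        wins_a.append(la[a_wins])
        wins_b.append(lb[~a_wins])
    p_a = float(per_experiment.mean())
    sd = float(per_experiment.std(ddof=1)) if n_experiments > 1 else 0.0
    return PreferencePrediction(
        pairing=(sample_a.option, sample_b.option),
        n_experiments=n_experiments,
        n_trials=n_trials,
        preference={sample_a.option: p_a, sample_b.option: 1.0 - p_a},
        mc_sd=sd,
        mc_se=sd / np.sqrt(n_experiments),
        winner_latencies={
            sample_a.option: np.concatenate(wins_a) if wins_a else np.empty(0),
            sample_b.option: np.concatenate(wins_b) if wins_b else np.empty(0),
        },
        per_experiment=per_experiment,
    )


def _is_degenerate(dist) -> bool:
    return isinstance(dist, (int, float))


def analytic_preference(dist_a, dist_b, tol: float = 1e-10) -> float:
    """P(option a wins the race) for parametric latency laws.

    Accepts scipy frozen continuous distributions or plain floats (point
    masses). For continuous laws computes ``integral f_a(t) * S_b(t) dt`` by
    adaptive quadrature.
    """
    if _is_degenerate(dist_a) and _is_degenerate(dist_b):
        if dist_a == dist_b:
            return 0.5
        return 1.0 if dist_a < dist_b else 0.0
    if _is_degenerate(dist_a):
        return float(dist_b.sf(dist_a))
    if _is_degenerate(dist_b):
        return float(dist_a.cdf(dist_b))
    lo = min(dist_a.ppf(1e-12), dist_b.ppf(1e-12))
    hi = max(dist_a.ppf(1 - 1e-12), dist_b.ppf(1 - 1e-12))
    val, err = integrate.quad(
        lambda t: dist_a.pdf(t) * dist_b.sf(t),
        max(lo, 0.0),
        hi,
        epsabs=tol,
        epsrel=tol,
        limit=200,
    )
    if err > 1e-6:
        raise RuntimeError(
            f"quadrature did not converge (estimated error {err:.2e})"
        )
    return float(min(max(val, 0.0), 1.0))


def censored_latency_summary(
    prediction: PreferencePrediction, option: str
) -> CensoredSummary:
    """Summary of the latencies on trials the option won (the censored
    minima). An option that never wins returns an empty summary, not an
    error."""
    if option not in prediction.winner_latencies:
        raise KeyError(f"option {option!r} not in prediction {prediction.pairing}")
    w = prediction.winner_latencies[option]
    if w.size == 0:
        return CensoredSummary(option=option, n_wins=0, median=None, empty=True)
    return CensoredSummary(
        option=option, n_wins=int(w.size), median=float(np.median(w)), empty=False
    )
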