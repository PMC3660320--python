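"""Configuration objects for the foraging-choice simulation and analysis pipeline.

All tunables live here, grouped in namespaces that mirror the pipeline stages:
``design`` (session structure), ``value`` (latency generator), ``timing``
(peak-trial pecking), ``scm`` (race Monte Carlo) and ``analysis`` (statistics
and pipeline scale). A :class:`FullConfig` bundles them and round-trips
through YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "OptionSpec",
    "DesignConfig",
    "ValueParams",
    "TimingParams",
    "ScmConfig",
    "AnalysisConfig",
    "FullConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class OptionSpec:
    """One foraging option: a stimulus signalling a fixed delay to food.

    ``rank`` is the ordinal of the option within its training context:
    1 for the better (shorter-delay) option, 2 for the worse.
    """

    id: str
    delay: float
    context: str
    rank: int

    def __post_init__(self) -> None:
        if self.delay <= 0:
            raise ValueError(f"option {self.id!r}: delay must be > 0, got {self.delay}")
        if self.rank not in (1, 2):
            raise ValueError(f"option {self.id!r}: rank must be 1 or 2, got {self.rank}")


def _default_contexts() -> dict[str, tuple[OptionSpec, OptionSpec]]:
    return {
        "AB": (
            OptionSpec("A", 5.0, "AB", 1),
            OptionSpec("B", 10.0, "AB", 2),
        ),
        "CD": (
            OptionSpec("C", 10.0, "CD", 1),
            OptionSpec("D", 20.0, "CD", 2),
        ),
    }


@dataclass
class DesignConfig:
    """Structure of one experimental day.

    Defaults reproduce the two-context design: per context visit,
    ``singles_per_option`` no-choice trials for each of the two options plus
    ``peaks_per_option`` unrewarded probe trials, ITIs re-equalised every
    ``iti_window`` single-option trials against ``iti_max_sum`` (by default
    the theoretical maximum of the summed delays, window x max delay).
    """

    contexts: dict[str, tuple[OptionSpec, OptionSpec]] = field(
        default_factory=_default_contexts
    )
    singles_per_option: int = 20
    peaks_per_option: int = 2
    base_iti: float = 30.0
    iti_window: int = 5
    iti_max_sum: float | None = None
    subsessions_per_day: int = 4
    peak_duration: float = 60.0
    pellets_per_reward: int = 2
    pellet_mass: float = 0.020
    choice_pairs_per_context_visit: int = 2
    session_cap_hours: float = 6.5  # metadata only; no real-time clock

    def __post_init__(self) -> None:
        for name, count in (
            ("singles_per_option", self.singles_per_option),
            ("iti_window", self.iti_window),
            ("subsessions_per_day", self.subsessions_per_day),
            ("pellets_per_reward", self.pellets_per_reward),
            ("choice_pairs_per_context_visit", self.choice_pairs_per_context_visit),
        ):
            if int(count) != count or count <= 0:
                raise ValueError(f"{name} must be a positive integer, got {count}")
        if self.peaks_per_option < 0:
            raise ValueError("peaks_per_option must be >= 0")
        for ctx, opts in self.contexts.items():
            if len(opts) != 2:
                raise ValueError(f"context {ctx!r} must have exactly two options")
            a, b = opts
            if a.rank == b.rank:
                raise ValueError(f"context {ctx!r}: option ranks must be distinct")
            for o in opts:
                if o.context != ctx:
                    raise ValueError(
                        f"option {o.id!r} declares context {o.context!r}, "
                        f"listed under {ctx!r}"
                    )
        if self.iti_max_sum is None:
            self.iti_max_sum = self.iti_window * max(self.delay_set)

    @property
    def options(self) -> dict[str, OptionSpec]:
        return {o.id: o for opts in self.contexts.values() for o in opts}

    @property
    def delay_set(self) -> tuple[float, ...]:
        return tuple(sorted({o.delay for o in self.options.values()}))

    @property
    def trials_per_subsession(self) -> int:
        return 2 * self.singles_per_option + 2 * self.peaks_per_option

    @property
    def trials_per_day(self) -> int:
        return self.subsessions_per_day * self.trials_per_subsession

    @property
    def choice_trials_per_day(self) -> int:
        # testing phase: a pair of choice trials opens and closes every
        # context visit
        return self.subsessions_per_day * 2 * self.choice_pairs_per_context_visit

    def daily_food_maximum(self, basis: str = "all_trials") -> float:
        """Maximum grams of food obtainable in one day.

        ``basis='all_trials'`` multiplies the full daily trial count by the
        reward size (the conventional all-trials arithmetic); ``'rewarded_only'``
        excludes the unrewarded probe trials.
        """
        if basis == "all_trials":
            n = self.trials_per_day
        elif basis == "rewarded_only":
            n = self.trials_per_day - self.subsessions_per_day * 2 * self.peaks_per_option
        else:
            raise ValueError(f"unknown basis {basis!r}")
        return n * self.pellets_per_reward * self.pellet_mass


@dataclass
class ValueParams:
    """Map from option attributes to subjective value and latency.

    value = w_imm / delay + w_rank * (+1 if better-ranked else -1);
    latency = floor_t0 + LogNormal(scale_a - scale_b * value, sigma_log).

    Defaults are calibrated so that the closed-form medians for the default
    option set are ~0.566 s (A), ~0.655 s (C), ~0.766 s (B), ~2.06 s (D):
    near-equal A and C compressed against the reaction-time floor, and D
    more than twice B.
    """

    w_imm: float = 1.0
    w_rank: float = 0.01
    floor_t0: float = 0.564
    scale_a: float = 2.0
    scale_b: float = 40.0
    sigma_log: float = 1.0
    subject_sd: float = 0.05
    # demonstrative knob, default OFF: probability that a choice trial is
    # resolved by a value softmax instead of the latency race
    extra_route_weight: float = 0.0
    extra_route_temp: float = 0.02

    def __post_init__(self) -> None:
        if self.floor_t0 <= 0:
            raise ValueError("floor_t0 must be > 0")
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")
        if self.scale_b <= 0:
            raise ValueError("scale_b must be > 0")
        if not 0.0 <= self.extra_route_weight <= 1.0:
            raise ValueError("extra_route_weight must be in [0, 1]")


@dataclass
class TimingParams:
    """Peak-trial pecking generator: Gaussian bump over baseline with
    scalar spread (cv * delay)."""

    cv: float = 0.3
    rate_max: float = 2.0
    baseline: float = 0.1
    decay: float = 0.0

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        if not self.rate_max > self.baseline >= 0:
            raise ValueError("need rate_max > baseline >= 0")


@dataclass
class ScmConfig:
    """Race Monte Carlo defaults: 10,000 experiments of 48 trials per
    cross-context pairing (96 per experiment for the default two pairings)."""

    n_experiments: int = 10_000
    trials_per_pairing: int = 48
    pairings: tuple[tuple[str, str], ...] = (("A", "C"), ("B", "C"))

    @property
    def trials_per_experiment(self) -> int:
        return self.trials_per_pairing * len(self.pairings)


@dataclass
class AnalysisConfig:
    """Statistical thresholds and desk-scale pipeline sizes."""

    sd_threshold: float = 10.0  # percentage points, last three sessions
    trend_threshold: float = 5.0  # points/session; 'no visible trend'
    alpha: float = 0.05
    latency_near_equality_s: float = 0.15
    n_subjects: int = 7
    training_days: int = 2
    max_test_days: int = 20


@dataclass
class FullConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    value: ValueParams = field(default_factory=ValueParams)
    timing: TimingParams = field(default_factory=TimingParams)
    scm: ScmConfig = field(default_factory=ScmConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


# ---------------------------------------------------------------------------
# serialization

def _config_to_dict(cfg: FullConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # contexts serialize as {ctx: [option dicts]}
    d["design"]["contexts"] = {
        ctx: [dataclasses.asdict(o) for o in opts]
        for ctx, opts in cfg.design.contexts.items()
    }
    d["scm"]["pairings"] = [list(p) for p in cfg.scm.pairings]
    return d


def _design_from_dict(d: Mapping) -> DesignConfig:
    d = dict(d)
    if "contexts" in d:
        d["contexts"] = {
            ctx: tuple(OptionSpec(**o) for o in opts)
            for ctx, opts in d["contexts"].items()
        }
    return DesignConfig(**d)


def config_from_dict(d: Mapping) -> FullConfig:
    kwargs: dict = {}
    if "design" in d:
        kwargs["design"] = _design_from_dict(d["design"])
    if "value" in d:
        kwargs["value"] = ValueParams(**d["value"])
    if "timing" in d:
        kwargs["timing"] = TimingParams(**d["timing"])
    if "scm" in d:
        scm = dict(d["scm"])
        if "pairings" in scm:
            scm["pairings"] = tuple(tuple(p) for p in scm["pairings"])
        kwargs["scm"] = ScmConfig(**scm)
    if "analysis" in d:
        kwargs["analysis"] = AnalysisConfig(**d["analysis"])
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    return FullConfig(**kwargs)


def load_config(path: str | Path) -> FullConfig:
    """Load a :class:`FullConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return config_from_dict(data)


def save_config(cfg: FullConfig, path: str | Path) -> None:
    path = Path(path)
    d = _config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
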