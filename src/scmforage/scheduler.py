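"""Session scheduling: build and validate daily trial plans.

A day is a sequence of sub-sessions alternating between the two training
contexts. Each sub-session holds a pseudo-random interleaving of
single-option and peak trials (never two peak trials in a row). Testing
days additionally substitute the first and last two single-option slots of
every sub-session with pairs of cross-context choice trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import DesignConfig

__all__ = [
    "PlannedTrial",
    "SessionSchedule",
    "SchedulingError",
    "build_training_session",
    "build_testing_session",
    "adjust_iti",
    "validate_schedule",
]

SINGLE = "single"
PEAK = "peak"
CHOICE = "choice"
TRIAL_TYPES = (SINGLE, PEAK, CHOICE)

_MAX_SHUFFLE_RETRIES = 10_000


class SchedulingError(ValueError):
    """Raised when a schedule cannot be built under the configured constraints."""


@dataclass
class PlannedTrial:
    index: int
    subsession: int
    context: str
    trial_type: str
    option_left: str | None
    option_right: str | None
    planned_iti_s: float  # NaN marks slots whose ITI is adjusted at simulation time

    @property
    def options(self) -> tuple[str, ...]:
        return tuple(o for o in (self.option_left, self.option_right) if o is not None)


@dataclass
class SessionSchedule:
    trials: list[PlannedTrial]
    config: DesignConfig
    phase: str  # 'training' | 'testing'
    day_parity: int
    seed: int
    pairing: tuple[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def subsession(self, k: int) -> list[PlannedTrial]:
        return [t for t in self.trials if t.subsession == k]

    @property
    def n_subsessions(self) -> int:
        return 1 + max(t.subsession for t in self.trials)


def adjust_iti(recent_delays: Sequence[float], config: DesignConfig) -> float:
    """Equalised ITI for the trial closing a window of single-option trials.

    Returns ``base_iti + (iti_max_sum - sum(recent_delays))`` so that every
    window of ``iti_window`` single-option trials yields the same total
    delay + ITI time regardless of which options were scheduled.
    """
    if len(recent_delays) != config.iti_window:
        raise ValueError(
            f"expected {config.iti_window} delays, got {len(recent_delays)}"
        )
    delay_set = set(config.delay_set)
    for d in recent_delays:
        if d not in delay_set:
            raise ValueError(f"delay {d} not in configured delay set {sorted(delay_set)}")
    return config.base_iti + (config.iti_max_sum - float(sum(recent_delays)))


def _context_order(config: DesignConfig, day_parity: int) -> list[str]:
    ids = list(config.contexts)
    if day_parity % 2:
        ids = ids[::-1]
    return [ids[k % len(ids)] for k in range(config.subsessions_per_day)]


def _shuffle_no_adjacent_peaks(
    items: list[tuple[str, str]], rng: np.random.Generator
) -> list[tuple[str, str]]:
    n_peak = sum(1 for t, _ in items if t == PEAK)
    if n_peak > len(items) - n_peak + 1:
        raise SchedulingError(
            f"cannot interleave {n_peak} peak trials among "
            f"{len(items) - n_peak} other trials without adjacency"
        )
    items = list(items)
    for _ in range(_MAX_SHUFFLE_RETRIES):
        rng.shuffle(items)
        if not any(
            items[i][0] == PEAK and items[i + 1][0] == PEAK
            for i in range(len(items) - 1)
        ):
            return items
    raise SchedulingError("no valid trial ordering found (retry limit reached)")


class _SideAssigner:
    """Alternate presentation sides per option, with a seeded starting side."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._state: dict[str, int] = {}

    def next_side(self, option: str) -> int:
        if option not in self._state:
            self._state[option] = int(self._rng.integers(2))
        side = self._state[option]
        self._state[option] = 1 - side
        return side


def _build_day(
    config: DesignConfig,
    day_parity: int,
    seed: int,
    phase: str,
    pairing: tuple[str, str] | None,
) -> SessionSchedule:
    rng = np.random.default_rng(seed)
    sides = _SideAssigner(rng)
    trials: list[PlannedTrial] = []
    index = 0
    for sub_k, ctx in enumerate(_context_order(config, day_parity)):
        opts = config.contexts[ctx]
        slots: list[tuple[str, str]] = []
        for o in opts:
            slots += [(SINGLE, o.id)] * config.singles_per_option
            slots += [(PEAK, o.id)] * config.peaks_per_option
        slots = _shuffle_no_adjacent_peaks(slots, rng)

        if phase == "testing":
            assert pairing is not None
            single_pos = [i for i, (t, _) in enumerate(slots) if t == SINGLE]
            n_sub = 2 * config.choice_pairs_per_context_visit
            if len(single_pos) < n_sub:
                raise SchedulingError(
                    "not enough single-option slots to host choice trials"
                )
            half = n_sub // 2
            for i in single_pos[:half] + single_pos[-(n_sub - half):]:
                slots[i] = (CHOICE, "")

        singles_seen = 0
        for trial_type, opt_id in slots:
            iti = config.base_iti
            if trial_type == CHOICE:
                side0 = sides.next_side(pairing[0])
                lr = [None, None]
                lr[side0] = pairing[0]
                lr[1 - side0] = pairing[1]
                left, right = lr
            else:
                side = sides.next_side(opt_id)
                left = opt_id if side == 0 else None
                right = opt_id if side == 1 else None
                if trial_type == SINGLE:
                    singles_seen += 1
                    if singles_seen % config.iti_window == 0:
                        iti = math.nan  # equalised at simulation time
            trials.append(
                PlannedTrial(index, sub_k, ctx, trial_type, left, right, iti)
            )
            index += 1
    return SessionSchedule(
        trials=trials,
        config=config,
        phase=phase,
        day_parity=day_parity % 2,
        seed=seed,
        pairing=pairing,
        meta={
            "context_intervals_min": [45, 60, 45],
            "session_cap_hours": config.session_cap_hours,
        },
    )


def build_training_session(
    config: DesignConfig, day_parity: int, seed: int
) -> SessionSchedule:
    """One training day: ``subsessions_per_day`` context visits, each with
    20 single-option trials per option and 2 peak trials per option (defaults),
    in pseudo-random order with no two consecutive peak trials."""
    return _build_day(config, day_parity, seed, "training", None)


def build_testing_session(
    config: DesignConfig,
    pairing: tuple[str, str] | Sequence[str],
    day_parity: int,
    seed: int,
) -> SessionSchedule:
    """One testing day: the training structure with the first and last two
    single-option slots of every sub-session replaced by choice trials
    offering the (cross-context) ``pairing``."""
    pairing = tuple(pairing)
    if len(pairing) != 2 or pairing[0] == pairing[1]:
        raise SchedulingError(f"pairing must name two distinct options, got {pairing}")
    options = config.options
    for p in pairing:
        if p not in options:
            raise SchedulingError(f"unknown option {p!r} in pairing")
    if options[pairing[0]].context == options[pairing[1]].context:
        raise SchedulingError(
            f"pairing {pairing} is within-context; only cross-context choices "
            "exist in this design"
        )
    return _build_day(config, day_parity, seed, "testing", pairing)


def validate_schedule(
    schedule: SessionSchedule, config: DesignConfig | None = None
) -> list[str]:
    """Structural checks; returns a list of human-readable violations
    (empty when the schedule is well formed)."""
    config = config or schedule.config
    v: list[str] = []
    trials = schedule.trials
    if [t.index for t in trials] != list(range(len(trials))):
        v.append("trial indices are not 0..n-1 in order")

    n_sub = 1 + max(t.subsession for t in trials)
    if n_sub != config.subsessions_per_day:
        v.append(f"expected {config.subsessions_per_day} sub-sessions, found {n_sub}")

    prev_ctx = None
    for k in range(n_sub):
        sub = [t for t in trials if t.subsession == k]
        ctxs = {t.context for t in sub}
        if len(ctxs) != 1:
            v.append(f"sub-session {k}: mixed contexts {sorted(ctxs)}")
            continue
        ctx = sub[0].context
        if prev_ctx is not None and ctx == prev_ctx:
            v.append(f"sub-session {k}: context {ctx} repeats the previous one")
        prev_ctx = ctx

        if len(sub) != config.trials_per_subsession:
            v.append(
                f"sub-session {k}: {len(sub)} trials, "
                f"expected {config.trials_per_subsession}"
            )
        for a, b in zip(sub, sub[1:]):
            if a.trial_type == PEAK and b.trial_type == PEAK:
                v.append(
                    f"sub-session {k}: consecutive peak trials at indices "
                    f"{a.index}, {b.index}"
                )

        ctx_ids = {o.id for o in config.contexts.get(ctx, ())}
        n_peak = sum(1 for t in sub if t.trial_type == PEAK)
        if n_peak != 2 * config.peaks_per_option:
            v.append(
                f"sub-session {k}: {n_peak} peak trials, "
                f"expected {2 * config.peaks_per_option}"
            )
        for t in sub:
            if t.trial_type not in TRIAL_TYPES:
                v.append(f"trial {t.index}: unknown type {t.trial_type!r}")
            if t.trial_type == CHOICE:
                if len(t.options) != 2:
                    v.append(f"trial {t.index}: choice trial without two options")
            else:
                if len(t.options) != 1:
                    v.append(f"trial {t.index}: expected exactly one option")
                elif t.options[0] not in ctx_ids:
                    v.append(
                        f"trial {t.index}: option {t.options[0]!r} not in context {ctx}"
                    )

        non_peak = [t for t in sub if t.trial_type != PEAK]
        choice_pos = [i for i, t in enumerate(non_peak) if t.trial_type == CHOICE]
        if schedule.phase == "testing":
            n_sub_choice = 2 * config.choice_pairs_per_context_visit
            half = n_sub_choice // 2
            expected = list(range(half)) + list(
                range(len(non_peak) - (n_sub_choice - half), len(non_peak))
            )
            if choice_pos != expected:
                v.append(
                    f"sub-session {k}: choice trials at non-peak slots {choice_pos}, "
                    f"expected {expected}"
                )
        elif choice_pos:
            v.append(f"sub-session {k}: choice trials in a training schedule")

        n_single = sum(1 for t in sub if t.trial_type == SINGLE)
        expected_singles = 2 * config.singles_per_option
        if schedule.phase == "testing":
            expected_singles -= 2 * config.choice_pairs_per_context_visit
        if n_single != expected_singles:
            v.append(
                f"sub-session {k}: {n_single} single trials, expected {expected_singles}"
            )
        if schedule.phase == "training":
            for oid in ctx_ids:
                c = sum(
                    1
                    for t in sub
                    if t.trial_type == SINGLE and t.options == (oid,)
                )
                if c != config.singles_per_option:
                    v.append(
                        f"sub-session {k}: option {oid} has {c} single trials, "
                        f"expected {config.singles_per_option}"
                    )
    return v
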