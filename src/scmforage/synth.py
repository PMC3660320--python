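"""Synthetic subject behaviour.

Latencies to accept an option come from a shifted lognormal whose log-median
decreases linearly with the option's subjective value (immediacy plus
within-context rank). The additive floor plays the role of the motor
reaction time: high-value options compress against it, so options with a
2:1 immediacy ratio can produce near-identical medians while low-value
options spread far apart.

Choice trials are resolved generatively by the same race the analysis
assumes: one latency is drawn per offered option and the faster option is
taken. This makes the default synthetic world self-consistent with the
race-model predictor, which is what the end-to-end checks exploit.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable

import numpy as np
import pandas as pd

from .config import DesignConfig, OptionSpec, TimingParams, ValueParams
from .scheduler import CHOICE, PEAK, SINGLE, SessionSchedule, adjust_iti, validate_schedule

__all__ = [
    "subjective_value",
    "median_latency",
    "draw_latency",
    "generate_peak_curve",
    "simulate_subject",
    "fit_value_map",
    "TRIAL_LOG_COLUMNS",
]

#: realized-trial log schema (one row per trial)
TRIAL_LOG_COLUMNS = [
    "subject",
    "day",
    "phase",
    "trial_index",
    "subsession",
    "context",
    "trial_type",
    "option_left",
    "option_right",
    "latency_s",
    "chosen_option",
    "rewarded",
    "iti_s",
    "peck_times",
]


def subjective_value(option: OptionSpec, params: ValueParams) -> float:
    """w_imm * immediacy + w_rank * (+1 better / -1 worse within context)."""
    rank_term = 1.0 if option.rank == 1 else -1.0
    return params.w_imm / option.delay + params.w_rank * rank_term


def median_latency(value: float, params: ValueParams) -> float:
    """Closed-form median of the latency law at a given value."""
    return params.floor_t0 + float(np.exp(params.scale_a - params.scale_b * value))


def draw_latency(
    value: float,
    params: ValueParams,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Sample latencies: floor_t0 + LogNormal(scale_a - scale_b*value, sigma_log)."""
    mu = params.scale_a - params.scale_b * value
    draw = rng.lognormal(mean=mu, sigma=params.sigma_log, size=size)
    return params.floor_t0 + draw


def peak_intensity(t, delay: float, tparams: TimingParams):
    """Expected pecking rate (pecks/s) at time ``t`` of a peak trial."""
    t = np.asarray(t, dtype=float)
    spread = tparams.cv * delay
    bump = tparams.rate_max * np.exp(-((t - delay) ** 2) / (2.0 * spread**2))
    base = tparams.baseline * np.exp(-tparams.decay * np.maximum(0.0, t - delay))
    return base + bump


def generate_peak_curve(
    delay: float,
    tparams: TimingParams,
    rng: np.random.Generator,
    window: float = 60.0,
    dt: float = 0.01,
) -> np.ndarray:
    """Peck timestamps for one unrewarded probe trial.

    Bernoulli thinning of the intensity in ``dt`` steps (at most one peck per
    step, a crude refractory period); timestamps are jittered uniformly
    within their step.
    """
    if delay >= window:
        raise ValueError(f"delay {delay} must be shorter than the {window}-s window")
    steps = np.arange(0.0, window, dt)
    p = np.clip(peak_intensity(steps + dt / 2.0, delay, tparams) * dt, 0.0, 1.0)
    hit = rng.random(steps.size) < p
    return steps[hit] + rng.random(int(hit.sum())) * dt


def _race_choice(
    offered: Iterable[str],
    draws: dict[str, float],
    values: dict[str, float],
    params: ValueParams,
    rng: np.random.Generator,
) -> str:
    offered = list(offered)
    if params.extra_route_weight > 0 and rng.random() < params.extra_route_weight:
        # value-softmax shortcut route (demonstrative knob, default off)
        v = np.array([values[o] for o in offered]) / params.extra_route_temp
        v -= v.max()
        p = np.exp(v)
        p /= p.sum()
        return offered[int(rng.choice(len(offered), p=p))]
    lats = [draws[o] for o in offered]
    best = min(lats)
    winners = [o for o, l in zip(offered, lats) if l == best]
    return winners[int(rng.integers(len(winners)))] if len(winners) > 1 else winners[0]


def simulate_subject(
    schedule: SessionSchedule,
    vparams: ValueParams,
    tparams: TimingParams,
    seed: int,
    subject: str = "s1",
    day: int = 0,
) -> pd.DataFrame:
    """Play one subject through one day's schedule.

    Returns a trial log (one row per trial, :data:`TRIAL_LOG_COLUMNS`).
    Single trials draw one latency and end rewarded; peak trials draw a
    latency plus a peck train and end unrewarded; choice trials draw one
    latency per offered option and the race picks the faster one. ITIs of
    equalisation slots are filled from the realized single-option delays.
    """
    violations = validate_schedule(schedule)
    if violations:
        raise ValueError(
            "refusing to simulate an invalid schedule: " + "; ".join(violations[:3])
        )
    config = schedule.config
    rng = np.random.default_rng(seed)
    subj_params = replace(
        vparams, scale_a=vparams.scale_a + rng.normal(0.0, vparams.subject_sd)
    )
    options = config.options
    values = {oid: subjective_value(o, subj_params) for oid, o in options.items()}

    rows = []
    recent_single_delays: list[float] = []
    current_sub = -1
    for t in schedule.trials:
        if t.subsession != current_sub:
            # contexts are separated by long breaks; the equalisation window
            # does not span sub-sessions
            recent_single_delays = []
            current_sub = t.subsession
        peck_times = None
        chosen = None
        rewarded = False
        iti = t.planned_iti_s
        if t.trial_type == SINGLE:
            oid = t.options[0]
            latency = float(draw_latency(values[oid], subj_params, rng))
            rewarded = True
            recent_single_delays.append(options[oid].delay)
            if np.isnan(iti):
                iti = adjust_iti(recent_single_delays[-config.iti_window :], config)
        elif t.trial_type == PEAK:
            oid = t.options[0]
            latency = float(draw_latency(values[oid], subj_params, rng))
            peck_times = generate_peak_curve(
                options[oid].delay, tparams, rng, window=config.peak_duration
            )
        elif t.trial_type == CHOICE:
            draws = {
                o: float(draw_latency(values[o], subj_params, rng)) for o in t.options
            }
            chosen = _race_choice(t.options, draws, values, subj_params, rng)
            latency = draws[chosen]
            rewarded = True
        else:  # pragma: no cover - schedule already validated
            raise ValueError(f"unknown trial type {t.trial_type!r}")
        rows.append(
            {
                "subject": subject,
                "day": day,
                "phase": schedule.phase,
                "trial_index": t.index,
                "subsession": t.subsession,
                "context": t.context,
                "trial_type": t.trial_type,
                "option_left": t.option_left,
                "option_right": t.option_right,
                "latency_s": latency,
                "chosen_option": chosen,
                "rewarded": rewarded,
                "iti_s": float(iti),
                "peck_times": peck_times,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def fit_value_map(
    log: pd.DataFrame, config: DesignConfig, vparams: ValueParams
) -> dict[str, float]:
    """Recover the value-to-latency map from a subject's single-option trials.

    Method of moments on log(latency - floor): per-option means regressed on
    the known option values give ``scale_b`` (negated slope) and ``scale_a``
    (intercept); the pooled within-option standard deviation estimates
    ``sigma_log``. The floor is taken as known.
    """
    singles = log[log["trial_type"] == SINGLE]
    if singles.empty:
        raise ValueError("no single-option trials in log")
    opt_col = singles["option_left"].fillna(singles["option_right"])
    vals, mus, resid = [], [], []
    for oid, grp in singles.groupby(opt_col):
        x = np.log(np.maximum(grp["latency_s"].to_numpy() - vparams.floor_t0, 1e-12))
        vals.append(subjective_value(config.options[oid], vparams))
        mus.append(x.mean())
        resid.append(x - x.mean())
    if len(vals) < 2:
        raise ValueError("need at least two options to identify the slope")
    slope, intercept = np.polyfit(vals, mus, 1)
    pooled = np.concatenate(resid)
    return {
        "scale_b": -float(slope),
        "scale_a": float(intercept),
        "sigma_log": float(pooled.std(ddof=len(vals))),
    }
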