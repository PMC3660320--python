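"""End-to-end desk-scale reproduction pipeline.

Simulates a cohort of subjects through training and both cross-context
choice tests (order counterbalanced), gates each test on the stability
rule, predicts each subject's choice proportions from their own no-choice
latencies with the race Monte Carlo, and assembles the observed-versus-
predicted comparison plus the shortening and peak-timing analyses.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FullConfig
from .io import RunManifest
from .peaks import PeakFit, bin_responses, compare_peak_times, fit_peak
from .race import LatencySample, PreferencePrediction, predict_preference
from .scheduler import CHOICE, PEAK, SINGLE, build_testing_session, build_training_session
from .stats import preference_test, shortening, stability_check
from .synth import simulate_subject
from .config import _config_to_dict

__all__ = ["run_full_pipeline", "PairingResult", "SubjectResult", "PipelineResult"]


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint64)[0])


def _single_latencies(log: pd.DataFrame, option: str) -> np.ndarray:
    singles = log[log["trial_type"] == SINGLE]
    mask = (singles["option_left"] == option) | (singles["option_right"] == option)
    return singles.loc[mask, "latency_s"].to_numpy()


def _chosen_latencies(log: pd.DataFrame, option: str) -> np.ndarray:
    choices = log[log["trial_type"] == CHOICE]
    return choices.loc[choices["chosen_option"] == option, "latency_s"].to_numpy()


@dataclass
class PairingResult:
    subject: str
    pairing: tuple[str, str]
    sessions_run: int
    stable: bool
    observed: dict[str, float]  # option -> observed choice proportion
    n_choice_trials: int
    prediction: PreferencePrediction
    single_latencies: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    observed_shortening: dict[str, float] = field(default_factory=dict)
    predicted_shortening: dict[str, float] = field(default_factory=dict)
    single_medians: dict[str, float] = field(default_factory=dict)
    choice_medians: dict[str, float] = field(default_factory=dict)


@dataclass
class SubjectResult:
    subject: str
    pairing_order: tuple[tuple[str, str], ...]
    pairings: dict[tuple[str, str], PairingResult]
    peak_fits: dict[str, PeakFit]


@dataclass
class PipelineResult:
    subjects: list[SubjectResult]
    preferences: pd.DataFrame  # one row per subject x pairing
    regression: dict[str, float]  # slope/intercept/r of observed vs predicted
    preference_tests: dict[tuple[str, str], object]
    peak_comparisons: dict[tuple[str, str], object]
    manifest: RunManifest


def _run_subject(
    cfg: FullConfig, subj_idx: int, subj_ss: np.random.SeedSequence
) -> SubjectResult:
    design, analysis = cfg.design, cfg.analysis
    subject = f"s{subj_idx + 1}"
    rng = np.random.default_rng(subj_ss.spawn(1)[0])
    # subject heterogeneity: one scale_a offset per subject, then frozen
    vparams = replace(
        cfg.value,
        scale_a=cfg.value.scale_a + rng.normal(0.0, cfg.value.subject_sd),
        subject_sd=0.0,
    )

    logs: list[pd.DataFrame] = []
    day = 0
    for _ in range(analysis.training_days):
        sched = build_training_session(
            design, day_parity=(day + subj_idx) % 2, seed=_seed_int(subj_ss.spawn(1)[0])
        )
        logs.append(
            simulate_subject(
                sched, vparams, cfg.timing, _seed_int(subj_ss.spawn(1)[0]), subject, day
            )
        )
        day += 1

    order = cfg.scm.pairings if subj_idx % 2 == 0 else cfg.scm.pairings[::-1]
    pairing_results: dict[tuple[str, str], PairingResult] = {}
    for pairing in order:
        session_logs: list[pd.DataFrame] = []
        session_pcts: list[float] = []
        stable = False
        while len(session_logs) < analysis.max_test_days and not stable:
            sched = build_testing_session(
                design, pairing, (day + subj_idx) % 2, _seed_int(subj_ss.spawn(1)[0])
            )
            log = simulate_subject(
                sched, vparams, cfg.timing, _seed_int(subj_ss.spawn(1)[0]), subject, day
            )
            logs.append(log)
            session_logs.append(log)
            choices = log[log["trial_type"] == CHOICE]
            session_pcts.append(100.0 * (choices["chosen_option"] == pairing[0]).mean())
            day += 1
            if len(session_pcts) >= 3:
                stable = stability_check(
                    session_pcts, analysis.sd_threshold, analysis.trend_threshold
                ).stable

        at_stability = pd.concat(session_logs[-3:], ignore_index=True)
        choices = at_stability[at_stability["trial_type"] == CHOICE]
        p0 = float((choices["chosen_option"] == pairing[0]).mean())
        samples = {
            o: LatencySample(o, _single_latencies(at_stability, o), subject=subject)
            for o in pairing
        }
        prediction = predict_preference(
            samples[pairing[0]],
            samples[pairing[1]],
            n_trials=cfg.scm.trials_per_pairing,
            n_experiments=cfg.scm.n_experiments,
            seed=subj_ss.spawn(1)[0],
        )
        result = PairingResult(
            subject=subject,
            pairing=pairing,
            sessions_run=len(session_logs),
            stable=stable,
            observed={pairing[0]: p0, pairing[1]: 1.0 - p0},
            n_choice_trials=len(choices),
            prediction=prediction,
            single_latencies={o: samples[o].latencies for o in pairing},
        )
        for o in pairing:
            single = samples[o].latencies
            chosen = _chosen_latencies(at_stability, o)
            result.single_medians[o] = float(np.median(single))
            if chosen.size:
                result.observed_shortening[o] = shortening(single, chosen)
                result.choice_medians[o] = float(np.median(chosen))
            winners = prediction.winner_latencies[o]
            if winners.size:
                result.predicted_shortening[o] = shortening(single, winners)
        pairing_results[pairing] = result

    all_logs = pd.concat(logs, ignore_index=True)
    peak_trials = all_logs[all_logs["trial_type"] == PEAK]
    opt_col = peak_trials["option_left"].where(
        peak_trials["option_left"].notna(), peak_trials["option_right"]
    )
    peak_fits: dict[str, PeakFit] = {}
    for oid, grp in peak_trials.groupby(opt_col):
        trains = [p for p in grp["peck_times"] if p is not None]
        curve = bin_responses(trains, bin_width=1.0, window=design.peak_duration, option=oid)
        peak_fits[oid] = fit_peak(curve)
    return SubjectResult(
        subject=subject,
        pairing_order=tuple(order),
        pairings=pairing_results,
        peak_fits=peak_fits,
    )


def run_full_pipeline(
    cfg: FullConfig | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    make_figures: bool = False,
) -> PipelineResult:
    """Run the whole desk-scale experiment and analysis.

    Deterministic given (config, seed); ``seed`` overrides ``cfg.seed``.
    """
    cfg = cfg or FullConfig()
    root_seed = cfg.seed if seed is None else int(seed)
    manifest = RunManifest(seed=root_seed, config=_config_to_dict(cfg))
    root = np.random.SeedSequence(root_seed)
    subject_streams = root.spawn(cfg.analysis.n_subjects)

    t0 = time.perf_counter()
    subjects = [
        _run_subject(cfg, i, ss) for i, ss in enumerate(subject_streams)
    ]
    manifest.stages["simulate_and_predict_s"] = round(time.perf_counter() - t0, 3)

    rows = []
    for sr in subjects:
        for pairing, pr in sr.pairings.items():
            focal = pairing[1]  # the option shared across pairings by default
            rows.append(
                {
                    "subject": sr.subject,
                    "pairing": f"{pairing[0]}:{pairing[1]}",
                    "focal_option": focal,
                    "observed": pr.observed[focal],
                    "predicted": pr.prediction.preference[focal],
                    "n_choice_trials": pr.n_choice_trials,
                    "n_singles_0": len(pr.single_latencies[pairing[0]]),
                    "n_singles_1": len(pr.single_latencies[pairing[1]]),
                    "sessions_run": pr.sessions_run,
                    "stable": pr.stable,
                }
            )
    preferences = pd.DataFrame(rows)

    slope, intercept = np.polyfit(preferences["predicted"], preferences["observed"], 1)
    r = float(np.corrcoef(preferences["predicted"], preferences["observed"])[0, 1])
    regression = {"slope": float(slope), "intercept": float(intercept), "r": r}

    preference_tests = {}
    peak_comparisons = {}
    for pairing in cfg.scm.pairings:
        key = f"{pairing[0]}:{pairing[1]}"
        sub = preferences[preferences["pairing"] == key]
        preference_tests[pairing] = preference_test(sub["observed"].to_numpy(), 0.5)
        fits_a = [s.peak_fits[pairing[0]] for s in subjects if pairing[0] in s.peak_fits]
        fits_b = [s.peak_fits[pairing[1]] for s in subjects if pairing[1] in s.peak_fits]
        if len(fits_a) == len(fits_b) and len(fits_a) >= 2:
            peak_comparisons[pairing] = compare_peak_times(fits_a, fits_b)

    result = PipelineResult(
        subjects=subjects,
        preferences=preferences,
        regression=regression,
        preference_tests=preference_tests,
        peak_comparisons=peak_comparisons,
        manifest=manifest,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pref_path = outdir / "preferences.csv"
        preferences.to_csv(pref_path, index=False)
        manifest.record_file(pref_path)
        peak_rows = [
            {
                "subject": s.subject,
                "option": oid,
                "peak_time": f.peak_time,
                "peak_rate": f.peak_rate,
                "spread": f.spread,
                "baseline": f.baseline,
            }
            for s in subjects
            for oid, f in s.peak_fits.items()
        ]
        peaks_path = outdir / "peak_fits.csv"
        pd.DataFrame(peak_rows).to_csv(peaks_path, index=False)
        manifest.record_file(peaks_path)
        if make_figures:
            _scatter_figure(preferences, regression, outdir / "observed_vs_predicted.png")
        manifest.write(outdir / "manifest.json")
    return result


def _scatter_figure(preferences: pd.DataFrame, regression: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for key, grp in preferences.groupby("pairing"):
        ax.scatter(grp["predicted"], grp["observed"], label=key)
    xs = np.linspace(0, 1, 10)
    ax.plot(xs, xs, "k--", lw=0.8, label="identity")
    ax.plot(xs, regression["intercept"] + regression["slope"] * xs, "r-", lw=0.8)
    ax.set_xlabel("predicted preference (focal option)")
    ax.set_ylabel("observed preference (focal option)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
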