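"""Peak-procedure analysis: bin peck trains, fit peak curves, compare
remembered delays between options."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .stats import TestResult, _one_sample_t

__all__ = [
    "PeakCurve",
    "PeakFit",
    "NoPeakError",
    "bin_responses",
    "fit_peak",
    "smoothed_argmax",
    "compare_peak_times",
]


class NoPeakError(ValueError):
    """The response curve has no peak to fit."""


@dataclass
class PeakCurve:
    option: str
    bin_width: float
    window: float
    rates: np.ndarray  # pecks/s per bin, averaged over trials
    n_trials: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.rates.size) + 0.5) * self.bin_width

    @property
    def total_pecks(self) -> float:
        return float(self.rates.sum() * self.bin_width * self.n_trials)


@dataclass
class PeakFit:
    peak_time: float
    peak_rate: float  # fitted rate at the peak (baseline + amplitude)
    spread: float
    baseline: float
    residual: float  # RMS of fit residuals


def bin_responses(
    peck_timestamps: Sequence[float] | Sequence[Sequence[float]],
    bin_width: float = 1.0,
    window: float = 60.0,
    option: str = "",
) -> PeakCurve:
    """Average binned response rates over one or more peak trials.

    Accepts a single timestamp train or a list of trains; rates are
    count / (bin_width * n_trials) so that binning conserves total pecks.
    Pecks exactly at the window edge fall in the last bin.
    """
    first = peck_timestamps[0] if len(peck_timestamps) else None
    if first is None or np.isscalar(first):
        trains = [np.asarray(peck_timestamps, dtype=float)]
    else:
        trains = [np.asarray(t, dtype=float) for t in peck_timestamps]
    n_bins = int(round(window / bin_width))
    counts = np.zeros(n_bins)
    for train in trains:
        if train.size and (train.min() < 0 or train.max() > window):
            raise ValueError("peck timestamp outside the peak window")
        c, _ = np.histogram(train, bins=n_bins, range=(0.0, window))
        counts += c
    rates = counts / (bin_width * len(trains))
    return PeakCurve(
        option=option,
        bin_width=bin_width,
        window=window,
        rates=rates,
        n_trials=len(trains),
    )


def smoothed_argmax(curve: PeakCurve, k: int = 3) -> float:
    """Peak-time estimate: centre of the maximal bin after a k-bin moving
    average."""
    kernel = np.ones(k) / k
    smooth = np.convolve(curve.rates, kernel, mode="same")
    return float(curve.bin_centers[int(np.argmax(smooth))])


def _gauss_model(t, baseline, amplitude, peak_time, spread):
    return baseline + amplitude * np.exp(-((t - peak_time) ** 2) / (2.0 * spread**2))


def fit_peak(curve: PeakCurve) -> PeakFit:
    """Least-squares fit of constant baseline + Gaussian bump.

    Initialised from the smoothed argmax; raises :class:`NoPeakError` on a
    flat profile.
    """
    t = curve.bin_centers
    y = curve.rates
    if np.ptp(y) == 0:
        raise NoPeakError("flat response curve: no peak to fit")
    t0 = smoothed_argmax(curve)
    p0 = [max(y.min(), 1e-6), max(np.ptp(y), 1e-6), t0, max(curve.window / 10, 1.0)]
    bounds = (
        [0.0, 0.0, 0.0, 1e-3],
        [np.inf, np.inf, curve.window, curve.window],
    )
    try:
        popt, _ = curve_fit(_gauss_model, t, y, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:
        raise NoPeakError(f"peak fit failed to converge: {exc}") from exc
    baseline, amplitude, peak_time, spread = popt
    resid = y - _gauss_model(t, *popt)
    return PeakFit(
        peak_time=float(peak_time),
        peak_rate=float(baseline + amplitude),
        spread=float(spread),
        baseline=float(baseline),
        residual=float(np.sqrt(np.mean(resid**2))),
    )


def compare_peak_times(
    fits_a: Sequence[PeakFit], fits_b: Sequence[PeakFit]
) -> TestResult:
    """Paired t (two-tailed) on per-subject peak times for two options.

    A null result for equal-delay options argues against a temporal-memory
    distortion account of preference.
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("fits must be paired per subject (equal lengths)")
    if len(fits_a) < 2:
        raise ValueError("need at least two subjects")
    a = np.array([f.peak_time for f in fits_a])
    b = np.array([f.peak_time for f in fits_b])
    return _one_sample_t(a - b, 0.0)
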