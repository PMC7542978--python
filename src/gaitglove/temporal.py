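"""Frequency and delay analysis of component time courses and raw channels.

The central statistic is the signed frame delay between two component time
courses, estimated as the lag (bounded at +/-25 frames, half a 1 Hz cycle at
50 Hz) maximizing the magnitude of the normalized cross-correlation; the
share of runs whose delay magnitude falls inside a 1 s window is the
finger-gaiting fraction.  Channel-level frequencies come from inter-maximum
intervals after zero-phase FIR low-pass filtering at 10 Hz and unit-max
normalization, cross-checked against minima and zero crossings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import AnalysisError

__all__ = [
    "SpectrumResult",
    "DelayProfile",
    "GroupFrequencyTable",
    "component_spectrum",
    "mean_spectrum",
    "component_delay",
    "gaiting_fraction",
    "fir_lowpass",
    "sensor_frequency",
    "group_frequency_tests",
]

MAX_LAG_FRAMES = 25
GAITING_WINDOW_FRAMES = 50
FIR_CUTOFF_HZ = 10.0
FIR_ORDER = 50


@dataclass
class SpectrumResult:
    """Unit-max normalized magnitude spectrum and its peak."""

    freqs: np.ndarray
    power: np.ndarray
    peak_freq: float


@dataclass
class DelayProfile:
    """Signed frame delays for a cohort of runs between one component pair."""

    delays: np.ndarray  # integer frames, |d| <= max_lag
    max_lag: int = MAX_LAG_FRAMES
    window_frames: int = GAITING_WINDOW_FRAMES

    @property
    def within_window_fraction(self) -> float:
        return gaiting_fraction(self, self.window_frames)


def component_spectrum(tc: np.ndarray, rate: float = 50.0) -> SpectrumResult:
    """DFT magnitude spectrum of the mean-removed series, unit-max normalized.

    Peak frequency is the argmax over (0, rate/2]; no tapering, so an
    800-frame series at 50 Hz resolves 0.0625 Hz bins.
    """
    x = np.asarray(tc, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise AnalysisError("constant series has no spectral peak")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    mag = mag / mag.max()
    nonzero = freqs > 0
    peak = float(freqs[nonzero][np.argmax(mag[nonzero])])
    return SpectrumResult(freqs=freqs, power=mag, peak_freq=peak)


def mean_spectrum(tcs: list[np.ndarray], rate: float = 50.0) -> SpectrumResult:
    """Average of unit-max normalized spectra; peak of the cohort mean."""
    spectra = [component_spectrum(tc, rate) for tc in tcs]
    power = np.mean([s.power for s in spectra], axis=0)
    freqs = spectra[0].freqs
    nonzero = freqs > 0
    peak = float(freqs[nonzero][np.argmax(power[nonzero])])
    return SpectrumResult(freqs=freqs, power=power, peak_freq=peak)


def component_delay(
    a: np.ndarray, b: np.ndarray, max_lag: int = MAX_LAG_FRAMES
) -> int:
    """Signed frame lag maximizing |normalized cross-correlation|.

    Positive means ``b`` lags ``a``.  Ties are broken toward smaller |lag|,
    then toward the positive lag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AnalysisError("series must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise AnalysisError("zero-variance input: delay undefined")
    best_lag, best_val = 0, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), -l)):
        if lag >= 0:
            x, y = a[: a.size - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: b.size + lag]
        if x.std() == 0 or y.std() == 0:
            continue
        r = abs(float(np.corrcoef(x, y)[0, 1]))
        if r > best_val + 1e-12:
            best_val, best_lag = r, lag
    return best_lag


def gaiting_fraction(profile: DelayProfile, window: int = GAITING_WINDOW_FRAMES) -> float:
    """Share of runs whose |delay| is strictly inside ``window`` frames."""
    d = np.asarray(profile.delays)
    if d.size == 0:
        raise AnalysisError("empty delay profile")
    return float(np.mean(np.abs(d) < window))


def fir_lowpass(
    x: np.ndarray,
    rate: float = 50.0,
    cutoff: float = FIR_CUTOFF_HZ,
    order: int = FIR_ORDER,
) -> np.ndarray:
    """Zero-phase (forward-backward) Hamming-window FIR low-pass."""
    taps = signal.firwin(order + 1, cutoff, window="hamming", fs=rate)
    return signal.filtfilt(taps, [1.0], np.asarray(x, dtype=float))


def _peak_interval_freq(
    x: np.ndarray,
    rate: float,
    min_separation_s: float,
    prominence_frac: float,
    height_frac: float = 0.25,
) -> float | None:
    rng = np.ptp(x)
    if rng == 0:
        return None
    height = height_frac * x.max() if x.max() > 0 else None
    peaks, _ = signal.find_peaks(
        x,
        distance=max(int(round(min_separation_s * rate)), 1),
        prominence=prominence_frac * rng,
        height=height,
    )
    if peaks.size < 2:
        return None
    return float(rate / np.mean(np.diff(peaks)))


def sensor_frequency(
    series: np.ndarray,
    rate: float = 50.0,
    min_separation_s: float = 0.4,
    prominence_frac: float = 0.10,
    height_frac: float = 0.25,
    check_tolerance: float = 0.10,
) -> float:
    """Cycle frequency of one channel from mean inter-maximum interval.

    The series is FIR low-pass filtered at 10 Hz (zero-phase) and normalized
    to unit maximum magnitude; frequency is the reciprocal of the mean
    interval between detected maxima, cross-checked against the minima-based
    and upward-zero-crossing estimates (a warning is emitted when either
    deviates by more than ``check_tolerance`` relative).  Peaks must clear a
    minimum separation, a prominence floor and a height floor (fraction of
    the series maximum) so baseline noise bumps between cycles are ignored.
    """
    x = fir_lowpass(series, rate)
    x = x - x.mean()
    peak_mag = np.max(np.abs(x))
    if peak_mag == 0:
        raise AnalysisError("constant series: frequency undefined")
    x = x / peak_mag
    # analyse the dominant polarity: a channel driven by a negative loading
    # shows dips, not peaks, and its cycle markers live on the minima side
    if -x.min() > x.max():
        x = -x

    f_max = _peak_interval_freq(x, rate, min_separation_s, prominence_frac, height_frac)
    if f_max is None:
        raise AnalysisError("fewer than 2 detectable maxima")
    f_min = _peak_interval_freq(-x, rate, min_separation_s, prominence_frac, height_frac)
    crossings = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    f_zc = (
        float(rate / np.mean(np.diff(crossings))) if crossings.size >= 2 else None
    )
    for name, f_alt in (("minima", f_min), ("zero-crossing", f_zc)):
        if f_alt is not None and abs(f_alt - f_max) > check_tolerance * f_max:
            warnings.warn(
                f"{name} frequency estimate {f_alt:.3f} Hz deviates from "
                f"maxima estimate {f_max:.3f} Hz by more than "
                f"{check_tolerance:.0%}",
                stacklevel=2,
            )
    return f_max


@dataclass
class GroupFrequencyTable:
    """Per sensor-group and hand frequency statistics with between/within tests."""

    table: pd.DataFrame  # rows: group; cols: mean/sd per hand, rank-sum p
    friedman_p: dict[str, float]  # hand -> p across the three groups


def group_frequency_tests(per_run: pd.DataFrame) -> GroupFrequencyTable:
    """Between-hand rank-sum and within-hand Friedman tests of group means.

    ``per_run`` must have columns ``hand``, ``run_id``, ``group``, ``freq``
    where each row is one run's mean frequency over a sensor group's member
    channels.
    """
    required = {"hand", "run_id", "group", "freq"}
    if not required <= set(per_run.columns):
        raise AnalysisError(f"per-run table needs columns {sorted(required)}")
    groups = sorted(per_run["group"].unique())
    hands = sorted(per_run["hand"].unique())
    rows = []
    for g in groups:
        row: dict[str, float | str] = {"group": g}
        for h in hands:
            vals = per_run.query("group == @g and hand == @h")["freq"]
            if len(vals) < 2:
                raise AnalysisError(f"need >= 2 runs for group {g!r}, hand {h!r}")
            row[f"mean_{h}"] = float(vals.mean())
            row[f"sd_{h}"] = float(vals.std(ddof=1))
        if len(hands) == 2:
            a = per_run.query("group == @g and hand == @hands[0]")["freq"]
            b = per_run.query("group == @g and hand == @hands[1]")["freq"]
            row["ranksum_p"] = float(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
        rows.append(row)
    friedman: dict[str, float] = {}
    for h in hands:
        wide = (
            per_run[per_run["hand"] == h]
            .pivot(index="run_id", columns="group", values="freq")
            .dropna()
        )
        if wide.shape[1] >= 3:
            friedman[h] = float(
                stats.friedmanchisquare(*[wide[g] for g in groups]).pvalue
            )
    return GroupFrequencyTable(table=pd.DataFrame(rows), friedman_p=friedman)
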