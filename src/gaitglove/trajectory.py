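"""Segmentation and summary of 3D fingertip trajectories.

A manipulation cycle is delimited by consecutive maxima of a thumb-extension
scalar — by default the per-frame distance of the thumb tip from the
time-mean centroid of the 23-point hand model (a single-axis coordinate is
available as an alternative).  Each inter-peak interval yields one
trajectory per fingertip; summaries report per-trajectory repetition
frequency (1/duration) and speed (path length over duration, cm/s), an
arc-length-uniform 100-point resampled mean trajectory, and a 95%
chi-square covariance ellipsoid per resampled point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import chi2

from .errors import AnalysisError
from .glove_io import HandPointSeries

__all__ = [
    "Trajectory",
    "TrajectorySummary",
    "thumb_extension_scalar",
    "segment_trajectories",
    "resample_arclength",
    "summarize_trajectories",
]

N_RESAMPLE = 100
CONFIDENCE = 0.95


@dataclass
class Trajectory:
    """One fingertip's path between two consecutive thumb-extension maxima."""

    tip: str
    frames: np.ndarray  # (n, 3) mm
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise AnalysisError("trajectory duration must be positive")

    @property
    def path_length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.frames, axis=0), axis=1)))

    @property
    def speed_cm_s(self) -> float:
        return (self.path_length_mm / 10.0) / self.duration_s

    @property
    def frequency_hz(self) -> float:
        return 1.0 / self.duration_s


@dataclass
class TrajectorySummary:
    """Cohort summary of one tip's trajectories."""

    tip: str
    n_trajectories: int
    median_frequency_hz: float
    iqr_frequency_hz: tuple[float, float]
    median_speed_cm_s: float
    mean_trajectory: np.ndarray  # (100, 3) mm
    ellipsoid_cov: np.ndarray  # (100, 3, 3)
    ellipsoid_scale: float  # chi-square 95% quantile, 3 df
    degenerate_points: list[int] = field(default_factory=list)


def thumb_extension_scalar(
    series: HandPointSeries,
    mode: str = "centroid_distance",
    axis: int = 0,
    thumb_tip: str | None = None,
) -> np.ndarray:
    """Per-frame scalar whose maxima mark maximal thumb extension.

    ``centroid_distance``: distance of the thumb tip from the time-mean
    centroid of all 23 points.  ``axis``: a single coordinate of the thumb
    tip.
    """
    tip = thumb_tip or series.tip_points[0]
    xyz = series.point(tip)
    if mode == "centroid_distance":
        ref = series.points.mean(axis=(0, 1))
        return np.linalg.norm(xyz - ref, axis=1)
    if mode == "axis":
        return xyz[:, axis].copy()
    raise AnalysisError(f"unknown thumb-extension mode {mode!r}")


def segment_trajectories(
    series: HandPointSeries,
    mode: str = "centroid_distance",
    min_separation_s: float = 0.4,
    prominence_frac: float = 0.10,
) -> dict[str, list[Trajectory]]:
    """Cut the point series at thumb-extension maxima; one trajectory per tip
    and inter-peak interval."""
    scalar = thumb_extension_scalar(series, mode=mode)
    rng = np.ptp(scalar)
    if rng == 0:
        raise AnalysisError("stationary hand: no thumb-extension peaks")
    peaks, _ = signal.find_peaks(
        scalar,
        distance=max(int(round(min_separation_s * series.rate)), 1),
        prominence=prominence_frac * rng,
    )
    if peaks.size < 2:
        raise AnalysisError(
            f"found {peaks.size} thumb-extension maxima; need at least 2"
        )
    out: dict[str, list[Trajectory]] = {}
    for tip in series.tip_points:
        xyz = series.point(tip)
        trajs = []
        for a, b in zip(peaks[:-1], peaks[1:]):
            trajs.append(
                Trajectory(
                    tip=tip,
                    frames=xyz[a : b + 1].copy(),
                    duration_s=(b - a) / series.rate,
                )
            )
        out[tip] = trajs
    return out


def resample_arclength(frames: np.ndarray, n: int = N_RESAMPLE) -> np.ndarray:
    """Resample a polyline to ``n`` points uniform in cumulative arc length.

    Endpoints are preserved exactly; degenerate (zero-length) paths repeat
    the first point.
    """
    frames = np.asarray(frames, dtype=float)
    seg = np.linalg.norm(np.diff(frames, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(frames[:1], n, axis=0)
    target = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(target, s, frames[:, d]) for d in range(3)]
    )


def summarize_trajectories(
    trajs: list[Trajectory], n_resample: int = N_RESAMPLE
) -> TrajectorySummary:
    """Medians/IQRs, arc-length-resampled mean path and 95% error ellipsoids."""
    if len(trajs) < 3:
        raise AnalysisError("need at least 3 trajectories to summarize")
    tips = {t.tip for t in trajs}
    if len(tips) != 1:
        raise AnalysisError("summarize_trajectories expects a single tip")
    freqs = np.array([t.frequency_hz for t in trajs])
    speeds = np.array([t.speed_cm_s for t in trajs])
    resampled = np.stack([resample_arclength(t.frames, n_resample) for t in trajs])
    mean_traj = resampled.mean(axis=0)
    scale = float(chi2.ppf(CONFIDENCE, df=3))
    covs = np.empty((n_resample, 3, 3))
    degenerate: list[int] = []
    for i in range(n_resample):
        devs = resampled[:, i, :] - mean_traj[i]
        cov = devs.T @ devs / (len(trajs) - 1)
        covs[i] = cov
        if np.linalg.matrix_rank(cov, tol=1e-12) < 3:
            degenerate.append(i)
    return TrajectorySummary(
        tip=trajs[0].tip,
        n_trajectories=len(trajs),
        median_frequency_hz=float(np.median(freqs)),
        iqr_frequency_hz=(
            float(np.percentile(freqs, 25)),
            float(np.percentile(freqs, 75)),
        ),
        median_speed_cm_s=float(np.median(speeds)),
        mean_trajectory=mean_traj,
        ellipsoid_cov=covs,
        ellipsoid_scale=scale,
        degenerate_points=degenerate,
    )
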