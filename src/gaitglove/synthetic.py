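"""Synthetic glove runs and fingertip trajectories with known ground truth.

The generator emulates the latent structure the analysis assumes: K periodic
grasp-configuration components near 1 Hz, each a smooth raised-cosine pulse
train with a fixed sensor loading pattern and a sub-second phase delay,
superposed with white noise and mapped affinely into the calibrated
amplitude range [0, 1000].  Every stochastic draw is tied to one seed so a
given spec reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import SpecError, ValidationError
from .glove_io import (
    DEFAULT_RATE_HZ,
    POINTS_RATE_HZ,
    TIP_POINT_NAMES,
    HandPointSeries,
    SensorRun,
    default_layout,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "RunTruth",
    "default_loadings",
    "simulate_runs",
    "simulate_trajectory",
    "pulse_train",
    "wrap_delay_frames",
]

N_CHANNELS = 19
N_FRAMES = 800


def pulse_train(
    t: np.ndarray,
    freq: float,
    delay_s: float = 0.0,
    duty: float = 0.30,
    waveform: Literal["raised_cosine", "sine"] = "raised_cosine",
) -> np.ndarray:
    """Smooth periodic waveform with exactly one maximum per period.

    ``raised_cosine`` is a squared raised-cosine pulse occupying a ``duty``
    fraction of each period (zero elsewhere), peaking at ``t = delay_s + n/freq``.
    ``sine`` is a plain sinusoid, useful when orthogonal time courses are
    needed at quarter-period offsets.
    """
    if waveform == "sine":
        return np.sin(2.0 * np.pi * freq * (np.asarray(t) - delay_s))
    u = (np.asarray(t) - delay_s) * freq
    v = np.mod(u + 0.5, 1.0) - 0.5  # signed phase in [-0.5, 0.5), peak at 0
    s = np.zeros_like(v)
    inside = np.abs(v) < duty / 2.0
    s[inside] = (0.5 * (1.0 + np.cos(2.0 * np.pi * v[inside] / duty))) ** 2
    return s


def wrap_delay_frames(delta_frames: float, period_frames: float, max_lag: int) -> float:
    """Expected bounded-lag delay for a true offset on a periodic signal.

    Cross-correlation of two periodic trains with true offset ``delta_frames``
    peaks at every ``delta + n*period``; the estimator capped at ``max_lag``
    reports the alias of smallest magnitude inside the cap.
    """
    d = float(delta_frames)
    candidates = d + period_frames * np.arange(-10, 11)
    candidates = candidates[np.abs(candidates) <= max_lag + 0.5]
    if candidates.size == 0:
        raise ValueError("no alias of the true delay falls inside the lag cap")
    return float(candidates[np.argmin(np.abs(candidates))])


def default_loadings(orthogonalize: bool = True) -> np.ndarray:
    """Three qualitative grasp-configuration loading patterns over relevant19.

    Component 1: thumb opposition — positive thumb-cross/palm-arch against
    negative finger PIPs.  Component 2: finger flexion — positive finger
    MCP/PIP against negative thumb channels.  Component 3: a weaker mixed
    abduction/pressure pattern.  Rows are unit-norm; optional Gram-Schmidt
    makes them exactly orthogonal while preserving the sign structure.
    """
    layout = default_layout()
    labels = list(layout.relevant19)
    idx = {l: i for i, l in enumerate(labels)}
    L = np.zeros((3, N_CHANNELS))

    L[0, idx["Tcross"]] = 0.58
    L[0, idx["PArch"]] = 0.45
    for f in "IMRL":
        L[0, idx[f"PIP_{f}"]] = -0.30
    L[0, idx["MCP_T"]] = 0.12
    L[0, idx["PIP_T"]] = 0.10
    L[0, idx["P1"]] = -0.12

    for f in "IMRL":
        L[1, idx[f"MCP_{f}"]] = 0.40
        L[1, idx[f"PIP_{f}"]] = 0.05
    L[1, idx["MCP_T"]] = -0.32
    L[1, idx["PIP_T"]] = -0.28
    L[1, idx["Tcross"]] = -0.15

    for i, a in enumerate(("A1", "A2", "A3", "A4")):
        L[2, idx[a]] = 0.28 if i % 2 == 0 else 0.24
    L[2, idx["P2"]] = -0.38
    L[2, idx["P3"]] = -0.33
    L[2, idx["MCP_T"]] = 0.30
    L[2, idx["PIP_T"]] = 0.28
    for f in "IMRL":
        L[2, idx[f"PIP_{f}"]] = 0.20
        L[2, idx[f"MCP_{f}"]] = -0.15

    if orthogonalize:
        for k in range(3):
            for j in range(k):
                L[k] -= (L[k] @ L[j]) * L[j] / (L[j] @ L[j])
            L[k] /= np.linalg.norm(L[k])
    else:
        L /= np.linalg.norm(L, axis=1, keepdims=True)
    return L


@dataclass
class SyntheticSpec:
    """Parameters of the latent-component generative model."""

    n_components: int = 3
    base_freq: float = 1.0
    freq_jitter_sd: float = 0.02
    loadings: np.ndarray | None = None
    delays_s: np.ndarray | None = None
    amplitudes: np.ndarray | None = None
    noise_sd: float = 0.02
    duty: float = 0.30
    waveform: Literal["raised_cosine", "sine"] = "raised_cosine"
    subject_loading_sd: float = 0.02
    n_runs: int = 6
    n_subjects: int = 22
    hand: str = "right"
    seed: int = 0
    rate: float = DEFAULT_RATE_HZ
    n_frames: int = N_FRAMES

    def __post_init__(self) -> None:
        if self.loadings is None:
            self.loadings = default_loadings()[: self.n_components]
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.delays_s is None:
            self.delays_s = np.array([0.0, 0.33, 0.66])[: self.n_components]
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        if self.amplitudes is None:
            self.amplitudes = np.array([1.0, 0.65, 0.40])[: self.n_components]
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)

    def validate(self) -> None:
        K = self.n_components
        if self.loadings.shape != (K, N_CHANNELS):
            raise SpecError(
                f"loadings must be {K} x {N_CHANNELS}, got {self.loadings.shape}"
            )
        norms = np.linalg.norm(self.loadings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise SpecError(f"loading rows must be unit-norm, got norms {norms}")
        if self.delays_s.shape != (K,):
            raise SpecError("delays_s must have one entry per component")
        if np.any(self.delays_s < 0.0) or np.any(self.delays_s >= 1.0):
            raise SpecError("delays_s entries must lie in [0, 1.0) seconds")
        if self.amplitudes.shape != (K,):
            raise SpecError("amplitudes must have one entry per component")
        if np.any(np.diff(self.amplitudes) >= 0.0):
            raise SpecError("amplitudes must be strictly decreasing")
        if self.base_freq <= 0.0:
            raise SpecError("base_freq must be positive")
        if self.noise_sd < 0.0:
            raise SpecError("noise_sd must be non-negative")


@dataclass
class RunTruth:
    """Realized latent parameters of one emitted run."""

    subject_id: str
    hand: str
    run_index: int
    freq: float
    delays_s: np.ndarray
    amplitudes: np.ndarray
    loadings: np.ndarray  # realized per-run (subject-jittered) loadings
    scale: float  # affine map latent -> [0, 1000]
    offset: float

    def expected_delay_frames(self, i: int, j: int, max_lag: int = 25) -> float:
        """Bounded-lag delay expected between component time courses i and j."""
        delta = (self.delays_s[j] - self.delays_s[i]) * DEFAULT_RATE_HZ
        period = DEFAULT_RATE_HZ / self.freq
        return wrap_delay_frames(delta, period, max_lag)


@dataclass
class GroundTruth:
    """Per-run latent records for a simulated cohort, reproducible from seed."""

    spec: SyntheticSpec
    runs: list[RunTruth] = field(default_factory=list)

    def for_run(self, subject_id: str, run_index: int) -> RunTruth:
        for r in self.runs:
            if r.subject_id == subject_id and r.run_index == run_index:
                return r
        raise KeyError((subject_id, run_index))


def _subject_loadings(
    base: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    if sd <= 0.0:
        return base.copy()
    jittered = base + rng.normal(0.0, sd, size=base.shape)
    return jittered / np.linalg.norm(jittered, axis=1, keepdims=True)


def simulate_runs(spec: SyntheticSpec) -> tuple[list[SensorRun], GroundTruth]:
    """Emit ``n_subjects * n_runs`` analysis-ready runs plus their ground truth.

    Each channel is the loading-weighted superposition of delayed component
    pulse trains plus white noise, affinely rescaled into [50, 950] so the
    calibrated-range invariant holds with margin.  The same seed always
    yields identical matrices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    layout = default_layout().subset(default_layout().relevant19)
    t = np.arange(spec.n_frames) / spec.rate

    runs: list[SensorRun] = []
    truth = GroundTruth(spec=spec)
    for s in range(1, spec.n_subjects + 1):
        subject_id = f"S{s:02d}"
        loadings = _subject_loadings(spec.loadings, spec.subject_loading_sd, rng)
        for r in range(1, spec.n_runs + 1):
            freq = spec.base_freq + rng.normal(0.0, spec.freq_jitter_sd)
            freq = max(freq, 0.05)
            latent = np.zeros((spec.n_frames, N_CHANNELS))
            for k in range(spec.n_components):
                s_k = pulse_train(
                    t, freq, spec.delays_s[k], spec.duty, spec.waveform
                )
                latent += spec.amplitudes[k] * np.outer(s_k, loadings[k])
            if spec.noise_sd > 0.0:
                latent = latent + rng.normal(
                    0.0, spec.noise_sd, size=latent.shape
                )
            lo, hi = float(latent.min()), float(latent.max())
            if hi - lo < 1e-12:
                scale, offset = 1.0, 500.0 - lo
            else:
                scale = 900.0 / (hi - lo)
                offset = 50.0 - lo * scale
            data = latent * scale + offset
            runs.append(
                SensorRun(
                    data=data,
                    rate=spec.rate,
                    subject_id=subject_id,
                    hand=spec.hand,
                    run_index=r,
                    layout=layout,
                )
            )
            truth.runs.append(
                RunTruth(
                    subject_id=subject_id,
                    hand=spec.hand,
                    run_index=r,
                    freq=freq,
                    delays_s=spec.delays_s.copy(),
                    amplitudes=spec.amplitudes.copy(),
                    loadings=loadings.copy(),
                    scale=scale,
                    offset=offset,
                )
            )
    return runs, truth


# ---------------------------------------------------------------------------
# 3D fingertip loops
# ---------------------------------------------------------------------------

# template positions (mm) of the 18 non-tip points of the 23-point hand model
_BASE_POINTS: dict[str, tuple[float, float, float]] = {
    "wrist": (0.0, -80.0, 0.0),
    "palm_center": (0.0, -30.0, 0.0),
    "palm_ulnar": (25.0, -40.0, 0.0),
    "CMC_T": (-35.0, -45.0, -5.0),
    "MCP_T": (-50.0, -20.0, -10.0),
    "MCP_I": (-25.0, 10.0, 0.0),
    "MCP_M": (-5.0, 15.0, 0.0),
    "MCP_R": (15.0, 12.0, 0.0),
    "MCP_L": (33.0, 5.0, 0.0),
    "PIP_T": (-62.0, 0.0, -12.0),
    "PIP_I": (-28.0, 40.0, -5.0),
    "PIP_M": (-5.0, 48.0, -5.0),
    "PIP_R": (17.0, 43.0, -5.0),
    "PIP_L": (37.0, 30.0, -5.0),
    "DIP_I": (-30.0, 58.0, -12.0),
    "DIP_M": (-5.0, 68.0, -12.0),
    "DIP_R": (19.0, 60.0, -12.0),
    "DIP_L": (40.0, 43.0, -12.0),
}

# circle centres of the 5 tips (thumb first), displaced from the hand centroid
_TIP_CENTERS: dict[str, tuple[float, float, float]] = {
    "tip_T": (-75.0, 15.0, -20.0),
    "tip_I": (-30.0, 75.0, -20.0),
    "tip_M": (-5.0, 85.0, -20.0),
    "tip_R": (20.0, 75.0, -20.0),
    "tip_L": (45.0, 55.0, -20.0),
}

_TIP_PHASES = {name: p for name, p in zip(TIP_POINT_NAMES, (0.0, 1.3, 2.5, 3.7, 4.9))}


def simulate_trajectory(
    freq: float = 1.0,
    radii_cm: dict[str, float] | float = 2.0,
    n_frames: int = 370,
    rate: float = POINTS_RATE_HZ,
    noise_mm: float = 0.0,
    seed: int = 0,
    subject_id: str = "S10",
    hand: str = "right",
    run_index: int = 1,
) -> HandPointSeries:
    """Closed fingertip loops at ``freq`` around per-tip centres.

    Each tip traces a planar circle whose plane contains the radial direction
    away from the hand centroid, so the thumb-extension scalar (distance of
    the thumb tip from the time-mean centroid) has exactly one maximum per
    cycle.  Mean tip speed for radius r is 2*pi*r*freq.
    """
    if freq <= 0.0:
        raise ValidationError("freq must be positive")
    if rate <= 2.0 * freq:
        raise ValidationError(
            f"sampling rate {rate} Hz must exceed twice the loop frequency {freq} Hz"
        )
    if not isinstance(radii_cm, dict):
        radii_cm = {name: float(radii_cm) for name in TIP_POINT_NAMES}

    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / rate
    names = tuple(_BASE_POINTS) + TIP_POINT_NAMES
    pts = np.empty((n_frames, len(names), 3))
    base_centroid = np.mean(
        np.array(list(_BASE_POINTS.values()) + list(_TIP_CENTERS.values())), axis=0
    )
    for j, name in enumerate(names):
        if name in _BASE_POINTS:
            pts[:, j, :] = np.asarray(_BASE_POINTS[name])
        else:
            c = np.asarray(_TIP_CENTERS[name])
            r_mm = 10.0 * radii_cm.get(name, 0.0)
            e1 = c - base_centroid
            e1 = e1 / np.linalg.norm(e1)
            ez = np.array([0.0, 0.0, 1.0])
            e2 = np.cross(e1, ez)
            e2 = e2 / np.linalg.norm(e2)
            theta = 2.0 * np.pi * freq * t + _TIP_PHASES[name]
            pts[:, j, :] = (
                c
                + r_mm * np.cos(theta)[:, None] * e1
                + r_mm * np.sin(theta)[:, None] * e2
            )
    if noise_mm > 0.0:
        pts = pts + rng.normal(0.0, noise_mm, size=pts.shape)
    return HandPointSeries(
        points=pts,
        point_names=names,
        rate=rate,
        subject_id=subject_id,
        hand=hand,
        run_index=run_index,
    )
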