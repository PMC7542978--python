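"""Reading, writing and slicing of glove run matrices and 3D hand-point series.

The on-disk dialect is UTF-8 TSV.  Metadata travels in ``#key=value`` comment
lines preceding a single header row; data rows carry an explicit 1-based
``frame`` column for human readability while all in-memory indexing is
0-based.  Channel order in a file may be permuted; the reader normalizes to
the layout's canonical order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ChannelLookupError,
    FormatError,
    ParseError,
    SizeError,
    ValidationError,
)

__all__ = [
    "SensorLayout",
    "SensorRun",
    "HandPointSeries",
    "default_layout",
    "read_run",
    "write_run",
    "trim_run",
    "select_channels",
    "read_points",
    "write_points",
]

AMPLITUDE_MIN = 0.0
AMPLITUDE_MAX = 1000.0
DEFAULT_RATE_HZ = 50.0
POINTS_RATE_HZ = 36.97
N_HAND_POINTS = 23

#: Names of the five distal-phalanx end points in the 23-point hand model.
TIP_POINT_NAMES = ("tip_T", "tip_I", "tip_M", "tip_R", "tip_L")


@dataclass(frozen=True)
class SensorLayout:
    """Canonical ordering and role assignment of the 29 glove channels."""

    labels: tuple[str, ...]
    roles: Mapping[str, str]
    relevant19: tuple[str, ...]
    graph12: tuple[str, ...]
    canonical_positive: tuple[str, ...] = ()
    frequency_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValidationError("layout labels are not unique")
        label_set = set(self.labels)
        if not set(self.relevant19) <= label_set:
            raise ValidationError("relevant19 is not a subset of labels")
        if not set(self.graph12) <= set(self.relevant19):
            raise ValidationError("graph12 is not a subset of relevant19")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ChannelLookupError(f"unknown channel {label!r}") from None

    def indices(self, subset: Sequence[str]) -> list[int]:
        return [self.index(lbl) for lbl in subset]

    def subset(self, subset: Sequence[str]) -> "SensorLayout":
        """Layout restricted (and reordered) to ``subset``."""
        sub = tuple(subset)
        for lbl in sub:
            self.index(lbl)
        keep = set(sub)
        return SensorLayout(
            labels=sub,
            roles={k: v for k, v in self.roles.items() if k in keep},
            relevant19=tuple(l for l in sub if l in set(self.relevant19)),
            graph12=tuple(l for l in sub if l in set(self.graph12)),
            canonical_positive=tuple(
                l for l in sub if l in set(self.canonical_positive)
            ),
            frequency_groups={
                g: tuple(l for l in members if l in keep)
                for g, members in self.frequency_groups.items()
            },
        )


def default_layout() -> SensorLayout:
    """The packaged 29-channel layout (bends, abductions, palm, pressures, quaternions)."""
    raw = json.loads(
        resources.files("gaitglove").joinpath("data/layout.json").read_text("utf-8")
    )
    return SensorLayout(
        labels=tuple(raw["labels"]),
        roles=dict(raw["roles"]),
        relevant19=tuple(raw["relevant19"]),
        graph12=tuple(raw["graph12"]),
        canonical_positive=tuple(raw["canonical_positive"]),
        frequency_groups={k: tuple(v) for k, v in raw["frequency_groups"].items()},
    )


@dataclass
class SensorRun:
    """One run: a frames x channels amplitude matrix plus acquisition metadata.

    Amplitudes are dimensionless calibrated units in [0, 1000].  A raw run is
    1000 frames at 50 Hz; analysis-ready runs carry exactly the last 800
    frames.
    """

    data: np.ndarray
    rate: float
    subject_id: str
    hand: str
    run_index: int
    layout: SensorLayout

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("run data must be 2-D (frames x channels)")
        if self.data.shape[1] != len(self.layout.labels):
            raise ValidationError(
                f"run has {self.data.shape[1]} columns but layout declares "
                f"{len(self.layout.labels)} channels"
            )
        if self.hand not in ("left", "right"):
            raise ValidationError(f"hand must be 'left' or 'right', got {self.hand!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("run data contains non-finite values")
        lo, hi = float(self.data.min(initial=0.0)), float(self.data.max(initial=0.0))
        if lo < AMPLITUDE_MIN or hi > AMPLITUDE_MAX:
            raise ValidationError(
                f"amplitudes outside [0, 1000]: observed range [{lo}, {hi}]"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def channels(self) -> tuple[str, ...]:
        return self.layout.labels

    def channel(self, label: str) -> np.ndarray:
        """One channel's time series as a 1-D view."""
        return self.data[:, self.layout.index(label)]


@dataclass
class HandPointSeries:
    """Per-frame x,y,z positions (mm) of the 23 standardized hand-model points."""

    points: np.ndarray  # (frames, 23, 3)
    point_names: tuple[str, ...]
    rate: float
    subject_id: str
    hand: str
    run_index: int
    tip_points: tuple[str, ...] = TIP_POINT_NAMES

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValidationError("points must have shape (frames, n_points, 3)")
        if self.points.shape[1] != len(self.point_names):
            raise ValidationError("point_names length does not match points array")
        if not set(self.tip_points) <= set(self.point_names):
            raise ValidationError("tip_points must be a subset of point_names")
        if len(self.tip_points) != 5:
            raise ValidationError("exactly 5 tip points are required")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    def point(self, name: str) -> np.ndarray:
        """(frames, 3) trajectory of one named point."""
        try:
            j = self.point_names.index(name)
        except ValueError:
            raise ChannelLookupError(f"unknown point {name!r}") from None
        return self.points[:, j, :]


# ---------------------------------------------------------------------------
# run files
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> tuple[dict[str, str], list[str], list[list[str]]]:
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
            else:
                rows.append(cells)
    if header is None:
        raise FormatError(f"{path}: no header row found")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return meta, header, rows


def _parse_float(cell: str, row: int, col: str, path: Path) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric cell {cell!r} at data row {row}, column {col!r}"
        ) from None


def read_run(path: str | Path, layout: SensorLayout | None = None) -> SensorRun:
    """Read a run TSV into a :class:`SensorRun` in canonical channel order.

    The file must carry all layout channels in its header (any order) plus an
    optional leading ``frame`` column.  Metadata comes from ``#key=value``
    lines (``subject``, ``hand``, ``run``, ``rate``).
    """
    path = Path(path)
    if layout is None:
        layout = default_layout()
    meta, header, rows = _read_table(path)

    cols = list(header)
    frame_col = None
    if cols and cols[0].lower() == "frame":
        frame_col = 0
        cols = cols[1:]
    seen: set[str] = set()
    for c in cols:
        if c in seen:
            raise FormatError(f"{path}: duplicate channel {c!r} in header")
        seen.add(c)
    missing = [l for l in layout.labels if l not in seen]
    if missing:
        raise FormatError(f"{path}: missing channel {missing[0]!r}")
    extra = [c for c in cols if c not in set(layout.labels)]
    if extra:
        raise FormatError(f"{path}: unknown channel {extra[0]!r}")

    n_cells = len(header)
    data = np.empty((len(rows), len(cols)))
    for i, row in enumerate(rows):
        if len(row) != n_cells:
            raise FormatError(
                f"{path}: row {i + 1} has {len(row)} cells, expected {n_cells}"
            )
        body = row if frame_col is None else row[1:]
        for j, cell in enumerate(body):
            data[i, j] = _parse_float(cell, i + 1, cols[j], path)

    # normalize to canonical order
    order = [cols.index(l) for l in layout.labels]
    data = data[:, order]

    return SensorRun(
        data=data,
        rate=float(meta.get("rate", DEFAULT_RATE_HZ)),
        subject_id=str(meta.get("subject", path.stem)),
        hand=str(meta.get("hand", "right")),
        run_index=int(meta.get("run", 1)),
        layout=layout,
    )


def write_run(run: SensorRun, path: str | Path) -> Path:
    """Write a run to the TSV dialect; ``read_run`` inverts this exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#subject={run.subject_id}\n")
        fh.write(f"#hand={run.hand}\n")
        fh.write(f"#run={run.run_index}\n")
        fh.write(f"#rate={run.rate:g}\n")
        fh.write("frame\t" + "\t".join(run.layout.labels) + "\n")
        for i in range(run.n_frames):
            cells = "\t".join(repr(float(v)) for v in run.data[i])
            fh.write(f"{i + 1}\t{cells}\n")
    return path


def trim_run(run: SensorRun, keep_last: int = 800) -> SensorRun:
    """Restrict a run to its final ``keep_last`` frames, order preserved."""
    if keep_last > run.n_frames:
        raise SizeError(
            f"cannot keep last {keep_last} frames of a {run.n_frames}-frame run"
        )
    return replace(run, data=run.data[run.n_frames - keep_last:].copy())


def select_channels(run: SensorRun, subset: Sequence[str]) -> SensorRun:
    """Restrict and reorder columns to ``subset``; layout follows."""
    idx = run.layout.indices(subset)
    return replace(run, data=run.data[:, idx].copy(), layout=run.layout.subset(subset))


# ---------------------------------------------------------------------------
# 3D point files
# ---------------------------------------------------------------------------

def read_points(path: str | Path) -> HandPointSeries:
    """Read a hand-point TSV (frame, then <point>_x/_y/_z triplets) in mm."""
    path = Path(path)
    meta, header, rows = _read_table(path)
    if not header or header[0].lower() != "frame":
        raise FormatError(f"{path}: first column must be 'frame'")
    coord_cols = header[1:]
    if len(coord_cols) % 3 != 0:
        raise FormatError(
            f"{path}: expected triplets of coordinate columns, got {len(coord_cols)}"
        )
    names: list[str] = []
    for k in range(0, len(coord_cols), 3):
        base = coord_cols[k]
        if not base.endswith("_x"):
            raise FormatError(f"{path}: column {base!r} should end in '_x'")
        name = base[:-2]
        if coord_cols[k + 1] != f"{name}_y" or coord_cols[k + 2] != f"{name}_z":
            raise FormatError(f"{path}: inconsistent coordinate triplet for {name!r}")
        names.append(name)
    if len(names) != N_HAND_POINTS:
        raise FormatError(
            f"{path}: expected {N_HAND_POINTS} points, found {len(names)}"
        )
    pts = np.empty((len(rows), len(names), 3))
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row {i + 1} has {len(row)} cells, expected {len(header)}"
            )
        for k in range(len(names)):
            for d in range(3):
                pts[i, k, d] = _parse_float(
                    row[1 + 3 * k + d], i + 1, header[1 + 3 * k + d], path
                )
    return HandPointSeries(
        points=pts,
        point_names=tuple(names),
        rate=float(meta.get("rate", POINTS_RATE_HZ)),
        subject_id=str(meta.get("subject", path.stem)),
        hand=str(meta.get("hand", "right")),
        run_index=int(meta.get("run", 1)),
    )


def write_points(series: HandPointSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#subject={series.subject_id}\n")
        fh.write(f"#hand={series.hand}\n")
        fh.write(f"#run={series.run_index}\n")
        fh.write(f"#rate={series.rate:g}\n")
        cols = ["frame"]
        for name in series.point_names:
            cols += [f"{name}_x", f"{name}_y", f"{name}_z"]
        fh.write("\t".join(cols) + "\n")
        for i in range(series.n_frames):
            cells = "\t".join(repr(float(v)) for v in series.points[i].ravel())
            fh.write(f"{i + 1}\t{cells}\n")
    return path
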