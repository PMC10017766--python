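"""Cell motility, adhesion and myotube fusion metrics.

Tracks are sampled at a fixed imaging interval (TI, default 10 min), so
speeds are reported in um/TI: the Euclidean displacement between consecutive
observed time points.  Total displacement over an analysis window is the
cumulative path length over the first floor(duration / TI) intervals and is
computed only for cells observed in every frame of the window; incomplete
tracks raise a structured exclusion rather than being dropped silently.

Fusion scoring follows the standard myotube rule: an alpha-actinin-positive
region containing >= 3 nuclei is a myotube, 1-2 nuclei a myocyte.  Fusion
efficiency is the percentage of all nuclei in the field residing in
myotubes; myocyte nuclei count only in the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "MotilitySummary",
    "IncompleteTrackError",
    "interval_speeds",
    "mean_speed",
    "total_displacement",
    "DisplacementResult",
    "AdhesionAssay",
    "adhesion_percent",
    "EllipseRegion",
    "FusionField",
    "FusionResult",
    "fusion_efficiency",
]

DEFAULT_INTERVAL_MIN = 10.0


class IncompleteTrackError(ValueError):
    """Track lacks observations over the requested analysis window."""

    def __init__(self, cell_id, missing_frames):
        self.cell_id = cell_id
        self.missing_frames = tuple(missing_frames)
        super().__init__(
            f"cell {cell_id!r}: incomplete track, missing frames "
            f"{list(self.missing_frames)[:5]}..."
            if len(self.missing_frames) > 5
            else f"cell {cell_id!r}: incomplete track, missing frames "
                 f"{list(self.missing_frames)}"
        )


@dataclass
class TrackSet:
    """Fixed-interval cell trajectories.

    data : DataFrame with columns cell_id, frame, x, y (frames are integer
           multiples of the imaging interval; positions in um)
    interval_minutes : imaging interval TI
    """

    data: pd.DataFrame
    interval_minutes: float = DEFAULT_INTERVAL_MIN

    def __post_init__(self):
        required = {"cell_id", "frame", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"track table missing columns {sorted(missing)}")
        df = self.data.sort_values(["cell_id", "frame"]).reset_index(drop=True)
        if df.duplicated(["cell_id", "frame"]).any():
            raise ValueError("duplicate (cell_id, frame) rows")
        for col in ("x", "y"):
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite value in column {col}")
        self.data = df
        if self.interval_minutes <= 0:
            raise ValueError("interval must be positive")

    @property
    def cell_ids(self) -> list:
        return list(self.data["cell_id"].unique())

    @property
    def frame_range(self) -> tuple[int, int]:
        f = self.data["frame"]
        return int(f.min()), int(f.max())

    def track(self, cell_id) -> pd.DataFrame:
        return self.data[self.data["cell_id"] == cell_id]

    def is_complete(self, cell_id, frames: Sequence[int] | None = None) -> bool:
        """Whether the cell is observed in every frame (default: the global
        frame range of the set)."""
        if frames is None:
            lo, hi = self.frame_range
            frames = range(lo, hi + 1)
        have = set(self.track(cell_id)["frame"].astype(int))
        return set(frames) <= have

    def transformed(self, *, angle_rad: float = 0.0,
                    dx: float = 0.0, dy: float = 0.0) -> "TrackSet":
        """Rigidly rotate (about the origin) and translate all tracks."""
        df = self.data.copy()
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
        df["x"] = c * x - s * y + dx
        df["y"] = s * x + c * y + dy
        return TrackSet(df, self.interval_minutes)


def interval_speeds(track: pd.DataFrame) -> np.ndarray:
    """Speeds (um/TI) between consecutive observed frames of one track.

    A gap in the frame sequence yields no speed entry for the gap.
    """
    track = track.sort_values("frame")
    if len(track) < 2:
        raise ValueError("track needs >= 2 frames for speeds")
    frames = track["frame"].to_numpy(dtype=int)
    xy = track[["x", "y"]].to_numpy(dtype=float)
    consecutive = np.diff(frames) == 1
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return steps[consecutive]


@dataclass
class MotilitySummary:
    per_cell: pd.DataFrame  # cell_id, mean_speed, n_intervals, complete
    group_mean: float
    group_sd: float
    n_cells: int
    window_minutes: tuple[float, float] | None = None
    excluded: list = field(default_factory=list)

    def summary(self) -> str:
        win = (f" over [{self.window_minutes[0]:g}, {self.window_minutes[1]:g}) min"
               if self.window_minutes else "")
        return (
            f"Mean speed{win}: {self.group_mean:.3g} +- {self.group_sd:.3g} "
            f"um/TI (n = {self.n_cells} cells)"
        )


def mean_speed(
    tracks: TrackSet,
    window_minutes: tuple[float, float] | None = None,
) -> MotilitySummary:
    """Group mean +- SD of per-cell mean speeds.

    The speed of interval k (frames k -> k+1) is assigned to the start time
    k*TI; windows are half-open [t0, t1).
    """
    ti = tracks.interval_minutes
    if window_minutes is not None:
        t0, t1 = window_minutes
        if t1 <= t0:
            raise ValueError("empty analysis window")
        lo, hi = tracks.frame_range
        if t0 >= (hi + 1) * ti:
            raise ValueError("analysis window outside observation span")
    rows = []
    excluded = []
    for cid in tracks.cell_ids:
        tr = tracks.track(cid).sort_values("frame")
        frames = tr["frame"].to_numpy(dtype=int)
        xy = tr[["x", "y"]].to_numpy(dtype=float)
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        keep = np.diff(frames) == 1
        if window_minutes is not None:
            t = frames[:-1] * ti
            keep &= (t >= window_minutes[0]) & (t < window_minutes[1])
        sel = steps[keep]
        if sel.size == 0:
            excluded.append((cid, "no intervals in window"))
            continue
        rows.append({
            "cell_id": cid,
            "mean_speed": float(np.mean(sel)),
            "n_intervals": int(sel.size),
            "complete": tracks.is_complete(cid),
        })
    if not rows:
        raise ValueError("no cell has intervals inside the analysis window")
    per_cell = pd.DataFrame(rows)
    speeds = per_cell["mean_speed"].to_numpy()
    sd = float(np.std(speeds, ddof=1)) if speeds.size > 1 else 0.0
    return MotilitySummary(per_cell, float(np.mean(speeds)), sd,
                           int(speeds.size), window_minutes, excluded)


@dataclass(frozen=True)
class DisplacementResult:
    cell_id: object
    path_length_um: float   # cumulative step-by-step distance (headline)
    net_displacement_um: float  # straight-line start-to-end (secondary)
    n_intervals: int


def total_displacement(
    tracks: TrackSet,
    cell_id,
    duration_minutes: float = 15 * 60.0,
) -> DisplacementResult:
    """Cumulative path length over the first floor(duration/TI) intervals.

    At TI = 10 min a 15 h window is exactly 90 intervals.  The cell must be
    observed in every frame of the window; otherwise IncompleteTrackError is
    raised so exclusions are explicit.
    """
    ti = tracks.interval_minutes
    n_intervals = int(duration_minutes // ti)
    lo, _ = tracks.frame_range
    needed = range(lo, lo + n_intervals + 1)
    tr = tracks.track(cell_id).sort_values("frame")
    have = set(tr["frame"].astype(int))
    missing = [f for f in needed if f not in have]
    if missing:
        raise IncompleteTrackError(cell_id, missing)
    sel = tr[tr["frame"].isin(list(needed))]
    xy = sel[["x", "y"]].to_numpy(dtype=float)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    return DisplacementResult(cell_id, float(np.sum(steps)), net, n_intervals)


# ---------------------------------------------------------------------------
# adhesion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdhesionAssay:
    """Adherent-cell counts before and after dissociation buffer."""

    pre_count: int
    post_count: int

    def __post_init__(self):
        if self.pre_count < 0 or self.post_count < 0:
            raise ValueError("counts must be >= 0")


def adhesion_percent(assay: AdhesionAssay) -> float:
    """Percent of cells remaining adherent after dissociation."""
    if assay.pre_count == 0:
        raise ValueError("pre-dissociation count is zero")
    if assay.post_count > assay.pre_count:
        warnings.warn(
            "post-dissociation count exceeds pre-dissociation count",
            stacklevel=2,
        )
    return 100.0 * assay.post_count / assay.pre_count


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseRegion:
    """Axis-aligned elliptical alpha-actinin-positive region (um)."""

    cx: float
    cy: float
    semi_x: float
    semi_y: float
    label: int = 0

    def contains(self, x: float, y: float) -> bool:
        """Point-in-ellipse with the boundary counted as inside."""
        return ((x - self.cx) / self.semi_x) ** 2 + (
            (y - self.cy) / self.semi_y
        ) ** 2 <= 1.0 + 1e-12


@dataclass
class FusionField:
    """Nuclei coordinates plus alpha-actinin-positive regions.

    Membership uses the nucleus centroid; a nucleus belongs to at most one
    region (regions are non-overlapping by construction).
    """

    nuclei: np.ndarray  # (N, 2) um
    regions: tuple[EllipseRegion, ...]

    def __post_init__(self):
        self.nuclei = np.asarray(self.nuclei, dtype=float).reshape(-1, 2)
        self.regions = tuple(self.regions)

    @classmethod
    def from_label_mask(cls, nuclei, mask: np.ndarray,
                        um_per_px: float = 1.0) -> "MaskFusionField":
        return MaskFusionField(nuclei, mask, um_per_px)

    def membership(self) -> np.ndarray:
        """Region label per nucleus (0 = background)."""
        labels = np.zeros(len(self.nuclei), dtype=int)
        for i, (x, y) in enumerate(self.nuclei):
            for region in self.regions:
                if region.contains(x, y):
                    labels[i] = region.label
                    break
        return labels


@dataclass
class MaskFusionField:
    """Fusion field backed by an integer label mask (image code path)."""

    nuclei: np.ndarray
    mask: np.ndarray
    um_per_px: float = 1.0

    def __post_init__(self):
        self.nuclei = np.asarray(self.nuclei, dtype=float).reshape(-1, 2)
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError("label mask must be 2D")

    def membership(self) -> np.ndarray:
        h, w = self.mask.shape
        labels = np.zeros(len(self.nuclei), dtype=int)
        for i, (x, y) in enumerate(self.nuclei):
            col = int(round(x / self.um_per_px))
            row = int(round(y / self.um_per_px))
            if 0 <= row < h and 0 <= col < w:
                labels[i] = int(self.mask[row, col])
        return labels


@dataclass(frozen=True)
class FusionResult:
    efficiency_percent: float
    n_nuclei: int
    n_in_myotubes: int
    region_table: pd.DataFrame  # label, n_nuclei, classification

    def summary(self) -> str:
        n_tubes = int((self.region_table["classification"] == "myotube").sum())
        n_cytes = int((self.region_table["classification"] == "myocyte").sum())
        return (
            f"Fusion efficiency: {self.efficiency_percent:.3g}% "
            f"({self.n_in_myotubes}/{self.n_nuclei} nuclei in {n_tubes} "
            f"myotubes; {n_cytes} myocytes excluded from the numerator)"
        )


def fusion_efficiency(field) -> FusionResult:
    """Fusion efficiency with the >= 3-nuclei myotube rule.

    Accepts any object with ``nuclei`` and ``membership()`` (ellipse-based
    `FusionField` or mask-based `MaskFusionField`).
    """
    n_nuclei = len(field.nuclei)
    if n_nuclei == 0:
        raise ValueError("field contains no nuclei")
    labels = field.membership()
    rows = []
    n_in_myotubes = 0
    for label in sorted(set(labels) - {0}):
        count = int(np.sum(labels == label))
        cls = "myotube" if count >= 3 else "myocyte"
        if cls == "myotube":
            n_in_myotubes += count
        rows.append({"label": label, "n_nuclei": count, "classification": cls})
    table = pd.DataFrame(rows, columns=["label", "n_nuclei", "classification"])
    return FusionResult(
        100.0 * n_in_myotubes / n_nuclei, n_nuclei, n_in_myotubes, table
    )
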