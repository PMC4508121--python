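"""Trajectory containers, I/O, window aggregation and sampling-rate analysis.

The central container is :class:`TrajectorySet`: a *complete panel* of
positions — every animal has one (x, y) observation, in metres, at every
shared time index.  Downstream inference (occupancy models, co-occurrence
tests) assumes this completeness, so the reader drops animals with missing
time points rather than imputing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectorySet",
    "BoundingBox",
    "TrajectoryParseError",
    "read_trajectories",
    "write_trajectories",
    "windowed_median",
    "bounding_box",
    "interpolation_error",
    "InterpolationError",
]

DEFAULT_COLUMNS = {"animal": "animal", "time": "time", "x": "x", "y": "y"}


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file cannot be parsed into a complete panel."""


@dataclass
class BoundingBox:
    """Axis-aligned rectangular region (the sample space), in metres."""

    x_low: float
    x_high: float
    y_low: float
    y_high: float

    def __post_init__(self) -> None:
        if not (self.x_low < self.x_high and self.y_low < self.y_high):
            raise ValueError(
                f"degenerate bounding box: "
                f"[{self.x_low}, {self.x_high}] x [{self.y_low}, {self.y_high}]"
            )

    @property
    def width(self) -> float:
        return self.x_high - self.x_low

    @property
    def height(self) -> float:
        return self.y_high - self.y_low

    def contains(self, x: float, y: float) -> bool:
        return (self.x_low <= x <= self.x_high) and (self.y_low <= y <= self.y_high)

    def to_dict(self) -> dict:
        return {
            "x_low": self.x_low,
            "x_high": self.x_high,
            "y_low": self.y_low,
            "y_high": self.y_high,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoundingBox":
        return cls(d["x_low"], d["x_high"], d["y_low"], d["y_high"])


@dataclass
class TrajectorySet:
    """Positions of N animals at H shared time points.

    Attributes
    ----------
    animal_ids:
        Opaque identifiers, length N.
    times:
        Strictly increasing integer-like time indices, length H.
    positions:
        Array of shape (H, N, 2) holding (x, y) in metres; all finite.
    """

    animal_ids: list = field(default_factory=list)
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 2)))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (H, N, 2)")
        H, N = self.positions.shape[:2]
        if len(self.animal_ids) != N:
            raise ValueError("animal_ids length does not match positions")
        if len(self.times) != H:
            raise ValueError("times length does not match positions")
        if H == 0 or N == 0:
            raise ValueError("empty trajectory set")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite position encountered")

    @property
    def n_animals(self) -> int:
        return self.positions.shape[1]

    @property
    def n_times(self) -> int:
        return self.positions.shape[0]

    @property
    def x(self) -> np.ndarray:
        """x-coordinates, shape (H, N)."""
        return self.positions[:, :, 0]

    @property
    def y(self) -> np.ndarray:
        """y-coordinates, shape (H, N)."""
        return self.positions[:, :, 1]

    def to_frame(self, columns: dict | None = None) -> pd.DataFrame:
        """Long-format DataFrame with one row per (animal, time)."""
        cols = {**DEFAULT_COLUMNS, **(columns or {})}
        H, N = self.positions.shape[:2]
        return pd.DataFrame(
            {
                cols["animal"]: np.repeat(self.animal_ids, H),
                cols["time"]: np.tile(self.times, N),
                cols["x"]: self.positions[:, :, 0].T.ravel(),
                cols["y"]: self.positions[:, :, 1].T.ravel(),
            }
        )


def read_trajectories(
    path,
    columns: dict | None = None,
    delimiter: str = ",",
    min_animals: int = 2,
) -> TrajectorySet:
    """Read a delimited trajectory table into a complete panel.

    Animals missing any shared time point are dropped with a warning; the
    shared time axis is the sorted union of times held by every remaining
    animal.  Malformed numeric fields (including literal ``NaN``) raise
    :class:`TrajectoryParseError` naming the offending line.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    for key in ("animal", "time", "x", "y"):
        if cols[key] not in df.columns:
            raise TrajectoryParseError(f"missing required column {cols[key]!r}")

    parsed = {}
    for key in ("time", "x", "y"):
        raw = df[cols[key]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna()
        if bad.any():
            # +2: one for the header line, one for 0- vs 1-based numbering
            line = int(bad.idxmax()) + 2
            raise TrajectoryParseError(
                f"malformed value {raw[bad.idxmax()]!r} in column "
                f"{cols[key]!r} at line {line}"
            )
        parsed[key] = vals
    animals = df[cols["animal"]]
    if animals.isna().any():
        line = int(animals.isna().idxmax()) + 2
        raise TrajectoryParseError(f"missing animal id at line {line}")

    tidy = pd.DataFrame(
        {"animal": animals, "time": parsed["time"], "x": parsed["x"], "y": parsed["y"]}
    )
    if tidy.duplicated(["animal", "time"]).any():
        raise TrajectoryParseError("duplicate (animal, time) rows")

    all_times = np.sort(tidy["time"].unique())
    counts = tidy.groupby("animal")["time"].nunique()
    complete = counts[counts == len(all_times)].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.warning(
            "dropping %d animal(s) with incomplete observations: %s",
            len(dropped),
            dropped,
        )
    if len(complete) < min_animals:
        raise TrajectoryParseError(
            f"only {len(complete)} complete animal(s); at least {min_animals} required"
        )

    tidy = tidy[tidy["animal"].isin(complete)]
    wide_x = tidy.pivot(index="time", columns="animal", values="x").sort_index()
    wide_y = tidy.pivot(index="time", columns="animal", values="y").sort_index()
    ids = list(wide_x.columns)
    positions = np.stack([wide_x.to_numpy(), wide_y.to_numpy()], axis=2)
    return TrajectorySet(ids, wide_x.index.to_numpy(), positions)


def write_trajectories(ts: TrajectorySet, path, columns: dict | None = None,
                       delimiter: str = ",") -> None:
    """Write a trajectory set to delimited text (inverse of the reader)."""
    ts.to_frame(columns).to_csv(path, sep=delimiter, index=False)


def windowed_median(ts: TrajectorySet, window_length: int) -> TrajectorySet:
    """Aggregate raw samples into per-window median observations.

    Windows are non-overlapping, aligned to the first time point; the
    trailing partial window is discarded.  Each output coordinate is the
    per-axis median of the raw coordinates in the window (even counts use
    the mean of the two middle order statistics), so the new panel has
    ``floor(H_raw / window_length)`` observations.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    H_raw = ts.n_times
    if window_length > H_raw:
        raise ValueError(
            f"window_length {window_length} exceeds number of samples {H_raw}"
        )
    H = H_raw // window_length
    trimmed = ts.positions[: H * window_length]
    windows = trimmed.reshape(H, window_length, ts.n_animals, 2)
    medians = np.median(windows, axis=1)
    new_times = ts.times[: H * window_length : window_length]
    return TrajectorySet(list(ts.animal_ids), new_times, medians)


def bounding_box(ts: TrajectorySet, padding: float = 0.0) -> BoundingBox:
    """Tight axis-aligned bounds of all positions, padded on each side.

    Raises if the padded box is degenerate (zero width or height), which
    happens only for collinear-on-an-axis data with zero padding.
    """
    x, y = ts.x, ts.y
    return BoundingBox(
        float(x.min() - padding),
        float(x.max() + padding),
        float(y.min() - padding),
        float(y.max() + padding),
    )


@dataclass
class InterpolationError:
    """Mean positional error of linear reconstruction after subsampling."""

    mean_error: float
    ci_low: float
    ci_high: float
    keep_fraction: float
    stride: int
    n_samples: int


def interpolation_error(ts: TrajectorySet, keep_fraction: float) -> InterpolationError:
    """Quantify the cost of a lower sampling rate by subsample-and-interpolate.

    Every k-th sample (k = round(1 / keep_fraction)) is marked valid; the
    rest are linearly interpolated between valid neighbours, with the first
    and last valid values repeated at the ends.  Returns the mean Euclidean
    distance between the reconstructed and original series over all samples
    (kept samples contribute zero), with a normal-approximation 95% CI.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    k = max(1, int(round(1.0 / keep_fraction)))
    H, N = ts.n_times, ts.n_animals
    t_idx = np.arange(H, dtype=float)
    valid = np.arange(0, H, k)

    recon = np.empty_like(ts.positions)
    for n in range(N):
        for axis in (0, 1):
            recon[:, n, axis] = np.interp(
                t_idx, t_idx[valid], ts.positions[valid, n, axis]
            )
    err = np.linalg.norm(recon - ts.positions, axis=2).ravel()
    mean = float(err.mean())
    if err.size > 1:
        half = 1.959963984540054 * float(err.std(ddof=1)) / np.sqrt(err.size)
    else:
        half = 0.0
    return InterpolationError(
        mean_error=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        keep_fraction=keep_fraction,
        stride=k,
        n_samples=int(err.size),
    )
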