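"""Partitions of the sample space and position-to-cell discretisation.

A :class:`Partition` is a finite set of axis-aligned rectangles that covers
the bounding region and is pairwise disjoint.  Disjointness is achieved
exactly with a half-open convention: a cell owns ``[low, high)`` on each
axis, except that cells touching the bounding box's upper x or y boundary
also own that closed edge (so the box's top/right border, and its upper
corner, belong to the outermost cells).

Two constructors are provided: a regular ``nx x ny`` grid of equal
rectangles, and a recursive balanced-split construction that adapts cell
size to the observation density — the cell holding the most observations is
repeatedly split perpendicular to its longer side at a coordinate chosen so
the two children hold as-equal-as-possible counts.  Heterogeneous habitats
(e.g. a popular feeding site) thus receive many small cells while empty
regions stay coarse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .trajectories import BoundingBox, TrajectorySet

__all__ = [
    "Partition",
    "OccupancySequences",
    "regular_partition",
    "irregular_partition",
    "locate",
    "locate_points",
    "discretise",
]


@dataclass
class Partition:
    """Disjoint covering set of rectangular cells over a bounding box.

    ``cells`` is a (D, 4) array with columns (x_low, x_high, y_low, y_high).
    Cell order is defined by the constructor that built the partition and is
    stable: row-major (y-major, then x) for regular grids; construction
    order for recursive splits (children appended as cells are divided).
    """

    cells: np.ndarray
    bbox: BoundingBox

    def __post_init__(self) -> None:
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=float))
        if self.cells.shape[1] != 4 or self.cells.shape[0] < 1:
            raise ValueError("cells must be a (D, 4) array with D >= 1")
        if np.any(self.cells[:, 0] >= self.cells[:, 1]) or np.any(
            self.cells[:, 2] >= self.cells[:, 3]
        ):
            raise ValueError("every cell must have positive width and height")

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"bbox": self.bbox.to_dict(), "cells": self.cells.tolist()}, indent=2
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "Partition":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(np.asarray(data["cells"]), BoundingBox.from_dict(data["bbox"]))


@dataclass
class OccupancySequences:
    """Cell index of each animal at each observation.

    ``indices`` has shape (H, N); entries are 0-based cell indices in
    ``range(D)``.  (Mathematical treatments index cells from 1; the 0-based
    convention here is the NumPy-native equivalent.)
    """

    indices: np.ndarray
    n_cells: int
    animal_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 2:
            raise ValueError("indices must have shape (H, N)")
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.n_cells
        ):
            raise ValueError("cell index out of range")
        if not self.animal_ids:
            self.animal_ids = list(range(self.indices.shape[1]))
        if len(self.animal_ids) != self.indices.shape[1]:
            raise ValueError("animal_ids length mismatch")

    @property
    def n_times(self) -> int:
        return self.indices.shape[0]

    @property
    def n_animals(self) -> int:
        return self.indices.shape[1]


def regular_partition(bbox: BoundingBox, nx: int, ny: int) -> Partition:
    """Tile the bounding box with an ``nx x ny`` grid of equal rectangles.

    Cells are ordered row-major: index = iy * nx + ix, with ix advancing
    fastest along increasing x.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be positive")
    xs = np.linspace(bbox.x_low, bbox.x_high, nx + 1)
    ys = np.linspace(bbox.y_low, bbox.y_high, ny + 1)
    cells = [
        (xs[ix], xs[ix + 1], ys[iy], ys[iy + 1])
        for iy in range(ny)
        for ix in range(nx)
    ]
    return Partition(np.asarray(cells), bbox)


def _split_candidates(coords: np.ndarray, low: float, high: float) -> np.ndarray:
    """Interior coordinates at which a half-open split is possible."""
    u = np.unique(coords)
    return u[(u > low) & (u < high)]


def _best_split(coords: np.ndarray, low: float, high: float):
    """Median-style split of ``coords`` at an observed interior coordinate.

    Returns (split_value, n_left) minimising the child-count imbalance,
    breaking ties toward the smaller left count; None if no interior
    coordinate exists (all points share one value on this axis).
    """
    cands = _split_candidates(coords, low, high)
    if cands.size == 0:
        return None
    coords_sorted = np.sort(coords)
    left_counts = np.searchsorted(coords_sorted, cands, side="left")
    # a split must leave observations on both sides, else it cannot balance
    keep = (left_counts > 0) & (left_counts < coords.size)
    if not keep.any():
        return None
    cands, left_counts = cands[keep], left_counts[keep]
    imbalance = np.abs(coords.size - 2 * left_counts)
    best = int(np.argmin(imbalance))  # argmin takes the first: smaller left count
    return float(cands[best]), int(left_counts[best])


def irregular_partition(
    data: TrajectorySet | np.ndarray, bbox: BoundingBox, n_cells: int
) -> Partition:
    """Recursive balanced splits: D cells with roughly equal observation counts.

    Observations of all animals are pooled.  Starting from the bounding box,
    ``n_cells - 1`` greedy splits are made; each step divides the cell with
    the largest count perpendicular to its longer side (ties split on x) at
    an observed coordinate equalising the children's counts as far as ties
    permit.  If the longer axis has no interior split coordinate, the other
    axis is tried; if neither splits, an error names the degenerate cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(data, TrajectorySet):
        points = data.positions.reshape(-1, 2)
    else:
        points = np.atleast_2d(np.asarray(data, dtype=float))
    if points.shape[1] != 2:
        raise ValueError("points must be (M, 2)")

    bounds = [(bbox.x_low, bbox.x_high, bbox.y_low, bbox.y_high)]
    members = [np.arange(points.shape[0])]

    for _ in range(n_cells - 1):
        target = int(np.argmax([m.size for m in members]))
        xl, xh, yl, yh = bounds[target]
        idx = members[target]
        axis_order = [0, 1] if (xh - xl) >= (yh - yl) else [1, 0]
        split = None
        for axis in axis_order:
            low, high = (xl, xh) if axis == 0 else (yl, yh)
            split = _best_split(points[idx, axis], low, high)
            if split is not None:
                break
        if split is None:
            raise ValueError(
                f"cannot split cell [{xl}, {xh}] x [{yl}, {yh}]: all "
                f"{idx.size} observation(s) coincide on both axes "
                "(requested cell count exceeds distinct positions)"
            )
        mid, _ = split
        mask = points[idx, axis] < mid
        if axis == 0:
            child_bounds = [(xl, mid, yl, yh), (mid, xh, yl, yh)]
        else:
            child_bounds = [(xl, xh, yl, mid), (xl, xh, mid, yh)]
        del bounds[target], members[target]
        bounds.extend(child_bounds)
        members.extend([idx[mask], idx[~mask]])

    return Partition(np.asarray(bounds), bbox)


def locate_points(p: Partition, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorised cell lookup for arrays of coordinates.

    Each point must lie inside the bounding box; membership is half-open
    ``[low, high)`` with the box's upper x/y boundary closed.
    """
    xs = np.asarray(xs, dtype=float).ravel()
    ys = np.asarray(ys, dtype=float).ravel()
    bb = p.bbox
    outside = (
        (xs < bb.x_low) | (xs > bb.x_high) | (ys < bb.y_low) | (ys > bb.y_high)
    )
    if outside.any():
        i = int(np.argmax(outside))
        raise ValueError(f"point ({xs[i]}, {ys[i]}) outside bounding box")

    xl, xh, yl, yh = p.cells.T
    in_x = (xs[:, None] >= xl) & (
        (xs[:, None] < xh) | ((xh == bb.x_high) & (xs[:, None] <= xh))
    )
    in_y = (ys[:, None] >= yl) & (
        (ys[:, None] < yh) | ((yh == bb.y_high) & (ys[:, None] <= yh))
    )
    hits = in_x & in_y
    counts = hits.sum(axis=1)
    if np.any(counts != 1):  # cover/disjoint violation would be a partition bug
        i = int(np.argmax(counts != 1))
        raise ValueError(
            f"point ({xs[i]}, {ys[i]}) contained in {counts[i]} cells"
        )
    return np.argmax(hits, axis=1)


def locate(p: Partition, x: float, y: float) -> int:
    """Index of the unique cell containing (x, y)."""
    return int(locate_points(p, [x], [y])[0])


def discretise(ts: TrajectorySet, p: Partition) -> OccupancySequences:
    """Map every position to its cell, giving the (H, N) occupancy matrix."""
    idx = locate_points(p, ts.x.ravel(), ts.y.ravel())
    return OccupancySequences(
        idx.reshape(ts.n_times, ts.n_animals), p.n_cells, list(ts.animal_ids)
    )
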