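"""Maximum-likelihood occupancy models over a spatial partition.

Two model families describe how an individual moves among the D cells of a
partition.  The categorical model ignores temporal order: a single
probability vector pi gives the chance of finding the animal in each cell
at any time, estimated by relative occupancy counts.  The Markov model adds
one step of temporal dependence: a column-stochastic transition matrix T
(entry (i, j) = probability of moving to cell i from cell j) and an initial
distribution p0, estimated by transition-count ratios, with p0 the point
mass at the first observed cell.

Either family can be fitted per animal or pooled across the group (one
shared pi or T).  A pooled Markov fit retains each animal's own point-mass
p0 so per-animal occupancy marginals still differ.

Columns of T for cells never departed from are genuinely undefined under
maximum likelihood; they are flagged and propagating probability mass into
such a cell raises rather than silently imputing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .partition import OccupancySequences

__all__ = [
    "CategoricalModel",
    "MarkovModel",
    "fit_categorical",
    "fit_markov",
    "occupancy_marginals",
]

_NORM_TOL = 1e-12


@dataclass
class CategoricalModel:
    """Time-homogeneous per-cell occupancy distribution."""

    pi: np.ndarray
    pooled: bool = False

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.ndim != 1:
            raise ValueError("pi must be a vector")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > _NORM_TOL:
            raise ValueError("pi must be a probability vector")

    @property
    def n_cells(self) -> int:
        return self.pi.size

    def to_json(self, path=None, **metadata) -> str:
        payload = json.dumps(
            {"kind": "categorical", "pi": self.pi.tolist(),
             "pooled": self.pooled, "metadata": metadata},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class MarkovModel:
    """First-order Markov occupancy model (T column-stochastic, p0 initial).

    ``undefined`` flags cells with no observed departures; the matching
    columns of T are NaN.  For a pooled fit ``p0`` is None and
    ``p0_by_animal`` holds one point-mass column per animal.
    """

    T: np.ndarray
    p0: np.ndarray | None = None
    p0_by_animal: np.ndarray | None = None
    undefined: np.ndarray = field(default=None)
    pooled: bool = False

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        D = self.T.shape[0]
        if self.T.shape != (D, D):
            raise ValueError("T must be square")
        if self.undefined is None:
            self.undefined = np.all(np.isnan(self.T), axis=0)
        self.undefined = np.asarray(self.undefined, dtype=bool)
        defined = ~self.undefined
        colsums = np.nansum(self.T[:, defined], axis=0)
        if defined.any() and np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("defined columns of T must sum to 1")
        if self.p0 is not None:
            self.p0 = np.asarray(self.p0, dtype=float)
            if abs(self.p0.sum() - 1.0) > _NORM_TOL:
                raise ValueError("p0 must sum to 1")
        if self.p0_by_animal is not None:
            self.p0_by_animal = np.asarray(self.p0_by_animal, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.T.shape[0]

    def initial_distribution(self, animal: int | None = None) -> np.ndarray:
        if self.p0 is not None:
            return self.p0
        if self.p0_by_animal is None or animal is None:
            raise ValueError("pooled Markov model needs an animal index for p0")
        return self.p0_by_animal[:, animal]

    def to_json(self, path=None, **metadata) -> str:
        payload = json.dumps(
            {
                "kind": "markov",
                "T": np.where(np.isnan(self.T), None, self.T).tolist(),
                "p0": None if self.p0 is None else self.p0.tolist(),
                "p0_by_animal": None
                if self.p0_by_animal is None
                else self.p0_by_animal.tolist(),
                "undefined": self.undefined.tolist(),
                "pooled": self.pooled,
                "metadata": metadata,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _occupancy_counts(occ: OccupancySequences, animal) -> np.ndarray:
    if animal == "pooled":
        seqs = occ.indices.ravel()
    else:
        seqs = occ.indices[:, animal]
    return np.bincount(seqs, minlength=occ.n_cells).astype(float)


def fit_categorical(occ: OccupancySequences, animal="pooled") -> CategoricalModel:
    """Categorical MLE: pi_i = C_i / sum(C), counts pooled when requested."""
    counts = _occupancy_counts(occ, animal)
    return CategoricalModel(counts / counts.sum(), pooled=animal == "pooled")


def _transition_counts(seq: np.ndarray, D: int) -> np.ndarray:
    num = np.zeros((D, D))
    np.add.at(num, (seq[1:], seq[:-1]), 1.0)
    return num


def fit_markov(
    occ: OccupancySequences, animal="pooled", pseudo_count: float = 0.0
) -> MarkovModel:
    """Markov MLE: T(i|j) = transitions j->i / departures from j.

    The denominator counts departures, i.e. the occupancy count of j minus
    one if the sequence ends in j.  ``pseudo_count`` optionally adds a flat
    additive count to every transition (off by default; the plain MLE is
    the reference behaviour) — useful only for degenerate pooled fits.
    """
    if occ.n_times < 2:
        raise ValueError("Markov fit needs at least 2 observations")
    D = occ.n_cells
    if animal == "pooled":
        num = np.zeros((D, D))
        for n in range(occ.n_animals):
            num += _transition_counts(occ.indices[:, n], D)
        p0_by_animal = np.zeros((D, occ.n_animals))
        p0_by_animal[occ.indices[0], np.arange(occ.n_animals)] = 1.0
        extra = dict(p0=None, p0_by_animal=p0_by_animal, pooled=True)
    else:
        num = _transition_counts(occ.indices[:, animal], D)
        p0 = np.zeros(D)
        p0[occ.indices[0, animal]] = 1.0
        extra = dict(p0=p0, p0_by_animal=None, pooled=False)

    if pseudo_count:
        num = num + pseudo_count
    departures = num.sum(axis=0)
    undefined = departures == 0
    T = np.full((D, D), np.nan)
    cols = ~undefined
    T[:, cols] = num[:, cols] / departures[cols]
    return MarkovModel(T=T, undefined=undefined, **extra)


def occupancy_marginals(model, H: int, animal: int | None = None) -> np.ndarray:
    """Per-time occupancy distributions, shape (H, D); each row sums to 1.

    Categorical models repeat pi.  Markov models propagate p_t = T p_{t-1}
    from the (animal's) initial distribution; reaching positive mass on a
    cell whose transition column was never observed raises, naming the
    cell, because the fitted model cannot be extended there.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    if isinstance(model, CategoricalModel):
        return np.tile(model.pi, (H, 1))
    if not isinstance(model, MarkovModel):
        raise TypeError(f"unsupported model type {type(model)!r}")

    p = model.initial_distribution(animal).copy()
    T = np.where(np.isnan(model.T), 0.0, model.T)
    out = np.empty((H, model.n_cells))
    out[0] = p
    for t in range(1, H):
        stuck = model.undefined & (p > 0)
        if stuck.any():
            cell = int(np.argmax(stuck))
            raise ValueError(
                f"cannot propagate past cell {cell}: no departures from it "
                "were observed, so its transition column is undefined"
            )
        p = T @ p
        out[t] = p
    return out
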