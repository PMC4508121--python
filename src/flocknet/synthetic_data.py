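"""Synthetic trajectory and occupancy generators with known affiliation truth.

Scenarios
---------
``null_categorical``
    Every animal draws its cell i.i.d. from a stated pi — the exact null of
    the categorical co-occurrence test.
``null_markov``
    Independent Markov chains from a stated (T, p0).
``hotspot_null``
    Independent i.i.d. draws from a pi concentrating ``hotspot_mass`` on
    the last cell (a popular feeding site), the rest uniform; still a true
    null, but in a heterogeneous environment.
``leader_follower``
    Animal 0 moves independently; every other animal copies the leader's
    current cell with probability rho, else draws independently.
``subflocks``
    One latent cell sequence per group (i.i.d. from pi, or a Markov chain
    when T is given); each member copies its group's latent cell with
    probability rho, else draws independently.  Within-group co-occurrence
    probability is inflated to roughly rho^2 + (1 - rho^2)/D while each
    animal's marginal stays pi, so the fitted null remains honest and the
    planted structure has a tunable effect size.  An optional flock-level
    coupling ``rho_between`` (default 0) adds a shared latent sequence that
    an animal copies, with that probability, whenever it did not copy its
    group latent — emulating a genuinely mixing flock in which sub-flock
    ties are stronger than, but do not exclude, flock-wide association.

Randomness is drawn from one named stream per animal (and per latent
group), derived from the master seed, so adding animals never perturbs
existing tracks and equal seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .partition import OccupancySequences, Partition
from .trajectories import BoundingBox, TrajectorySet

__all__ = ["SimConfig", "simulate", "continuous_walk", "occupancy_to_trajectories"]

SCENARIOS = (
    "null_categorical",
    "null_markov",
    "hotspot_null",
    "leader_follower",
    "subflocks",
)

# Offsets keeping per-animal, per-group and per-walk streams disjoint.
_ANIMAL_STREAM = 0
_GROUP_STREAM = 1 << 20
_WALK_STREAM = 1 << 21


@dataclass
class SimConfig:
    """Study conditions for a synthetic data set.

    Defaults mirror the reference experimental setup: 25 cells, 500
    observations, uniform occupancy under the null, hotspot mass 0.5
    (yielding pi = (0.25, 0.25, 0.5) at D = 3).
    """

    seed: int
    n_animals: int = 20
    n_times: int = 500
    n_cells: int = 25
    scenario: str = "null_categorical"
    rho: float = 0.0
    rho_between: float = 0.0
    hotspot_mass: float = 0.5
    group_sizes: tuple | None = None
    pi: np.ndarray | None = None
    T: np.ndarray | None = None
    p0: np.ndarray | None = None
    bbox: BoundingBox | None = None
    step_size: float = 1.0
    animal_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.rho_between <= 1.0:
            raise ValueError("rho_between must lie in [0, 1]")
        if not 0.0 < self.hotspot_mass < 1.0:
            raise ValueError("hotspot_mass must lie in (0, 1)")
        if self.n_animals < 1 or self.n_times < 1 or self.n_cells < 1:
            raise ValueError("n_animals, n_times, n_cells must be positive")
        if self.scenario == "subflocks":
            if self.group_sizes is None:
                half = self.n_animals // 2
                self.group_sizes = (half, self.n_animals - half)
            if sum(self.group_sizes) != self.n_animals:
                raise ValueError("group_sizes must sum to n_animals")
        if not self.animal_ids:
            self.animal_ids = [f"a{n:03d}" for n in range(self.n_animals)]

    def resolved_pi(self) -> np.ndarray:
        if self.pi is not None:
            pi = np.asarray(self.pi, dtype=float)
            if pi.size != self.n_cells or abs(pi.sum() - 1.0) > 1e-9:
                raise ValueError("pi must be a length-D probability vector")
            return pi
        if self.scenario == "hotspot_null":
            if self.n_cells < 2:
                raise ValueError("hotspot_null needs at least 2 cells")
            pi = np.full(
                self.n_cells, (1.0 - self.hotspot_mass) / (self.n_cells - 1)
            )
            pi[-1] = self.hotspot_mass
            return pi
        return np.full(self.n_cells, 1.0 / self.n_cells)

    def group_labels(self) -> np.ndarray:
        """Ground-truth group label per animal (subflocks scenario)."""
        if self.scenario != "subflocks":
            raise ValueError("group labels only defined for the subflocks scenario")
        return np.repeat(np.arange(len(self.group_sizes)), self.group_sizes)


def _animal_rng(seed: int, n: int, stream: int = _ANIMAL_STREAM):
    return np.random.default_rng([seed, stream + n])


def _iid_draws(rng, pi: np.ndarray, H: int) -> np.ndarray:
    return rng.choice(pi.size, size=H, p=pi)


def _chain_draws(rng, T: np.ndarray, p0: np.ndarray, H: int) -> np.ndarray:
    seq = np.empty(H, dtype=np.int64)
    seq[0] = rng.choice(p0.size, p=p0)
    for t in range(1, H):
        seq[t] = rng.choice(T.shape[0], p=T[:, seq[t - 1]])
    return seq


def _default_chain(D: int):
    """Sticky uniform chain: stay with probability 1/2, else jump uniformly."""
    T = np.full((D, D), 0.5 / D)
    T[np.diag_indices(D)] += 0.5
    return T, np.full(D, 1.0 / D)


def simulate(cfg: SimConfig) -> OccupancySequences:
    """Generate an occupancy panel under the configured scenario."""
    H, N, D = cfg.n_times, cfg.n_animals, cfg.n_cells
    pi = cfg.resolved_pi()
    indices = np.empty((H, N), dtype=np.int64)

    if cfg.scenario in ("null_categorical", "hotspot_null"):
        for n in range(N):
            indices[:, n] = _iid_draws(_animal_rng(cfg.seed, n), pi, H)

    elif cfg.scenario == "null_markov":
        if cfg.T is not None:
            T = np.asarray(cfg.T, dtype=float)
            p0 = (
                np.asarray(cfg.p0, dtype=float)
                if cfg.p0 is not None
                else np.full(D, 1.0 / D)
            )
        else:
            T, p0 = _default_chain(D)
        for n in range(N):
            indices[:, n] = _chain_draws(_animal_rng(cfg.seed, n), T, p0, H)

    elif cfg.scenario == "leader_follower":
        leader = _iid_draws(_animal_rng(cfg.seed, 0), pi, H)
        indices[:, 0] = leader
        for n in range(1, N):
            rng = _animal_rng(cfg.seed, n)
            own = _iid_draws(rng, pi, H)
            copy = rng.random(H) < cfg.rho
            indices[:, n] = np.where(copy, leader, own)

    elif cfg.scenario == "subflocks":
        if cfg.T is not None:
            T = np.asarray(cfg.T, dtype=float)
            p0 = (
                np.asarray(cfg.p0, dtype=float)
                if cfg.p0 is not None
                else np.full(D, 1.0 / D)
            )
            latents = [
                _chain_draws(_animal_rng(cfg.seed, g, _GROUP_STREAM), T, p0, H)
                for g in range(len(cfg.group_sizes))
            ]
        else:
            latents = [
                _iid_draws(_animal_rng(cfg.seed, g, _GROUP_STREAM), pi, H)
                for g in range(len(cfg.group_sizes))
            ]
        labels = cfg.group_labels()
        flock_latent = None
        if cfg.rho_between > 0:
            flock_latent = _iid_draws(
                _animal_rng(cfg.seed, len(cfg.group_sizes), _GROUP_STREAM), pi, H
            )
        for n in range(N):
            rng = _animal_rng(cfg.seed, n)
            own = _iid_draws(rng, pi, H)
            copy = rng.random(H) < cfg.rho
            seq = np.where(copy, latents[labels[n]], own)
            if flock_latent is not None:
                copy_flock = ~copy & (rng.random(H) < cfg.rho_between)
                seq = np.where(copy_flock, flock_latent, seq)
            indices[:, n] = seq

    return OccupancySequences(indices, D, list(cfg.animal_ids))


def continuous_walk(cfg: SimConfig) -> TrajectorySet:
    """Reflected Gaussian random walk per animal inside the bounding box.

    Couplings mirror :func:`simulate`: in ``leader_follower`` (or
    ``subflocks``, against the group's lowest-index member) a coupled
    animal's position is replaced by its target's current position with
    probability rho at each step, so rho = 1 duplicates the target's track.
    """
    if cfg.bbox is None:
        raise ValueError("continuous_walk requires cfg.bbox")
    if cfg.step_size < 0:
        raise ValueError("step_size must be non-negative")
    bb = cfg.bbox
    H, N = cfg.n_times, cfg.n_animals

    def reflect(v, low, high):
        span = high - low
        v = np.mod(v - low, 2 * span)
        return low + np.where(v > span, 2 * span - v, v)

    pos = np.empty((H, N, 2))
    for n in range(N):
        rng = _animal_rng(cfg.seed, n, _WALK_STREAM)
        start = np.array(
            [rng.uniform(bb.x_low, bb.x_high), rng.uniform(bb.y_low, bb.y_high)]
        )
        steps = rng.normal(0.0, cfg.step_size, size=(H - 1, 2)) if H > 1 else None
        track = np.empty((H, 2))
        track[0] = start
        for t in range(1, H):
            raw = track[t - 1] + steps[t - 1]
            track[t, 0] = reflect(raw[0], bb.x_low, bb.x_high)
            track[t, 1] = reflect(raw[1], bb.y_low, bb.y_high)
        pos[:, n] = track

    if cfg.scenario in ("leader_follower", "subflocks") and cfg.rho > 0:
        if cfg.scenario == "leader_follower":
            targets = np.zeros(N, dtype=int)
        else:
            labels = cfg.group_labels()
            firsts = [int(np.argmax(labels == g)) for g in range(len(cfg.group_sizes))]
            targets = np.array([firsts[g] for g in labels])
        for n in range(N):
            if targets[n] == n:
                continue
            rng = _animal_rng(cfg.seed, n)  # coupling stream, as in simulate()
            copy = rng.random(H) < cfg.rho
            pos[copy, n] = pos[copy, targets[n]]

    return TrajectorySet(list(cfg.animal_ids), np.arange(H), pos)


def occupancy_to_trajectories(
    occ: OccupancySequences, p: Partition, seed: int
) -> TrajectorySet:
    """Place each occupancy observation uniformly at random inside its cell."""
    rng = np.random.default_rng([seed, 3 << 20])
    cells = p.cells[occ.indices.ravel()]
    xs = rng.uniform(cells[:, 0], cells[:, 1])
    ys = rng.uniform(cells[:, 2], cells[:, 3])
    pos = np.stack([xs, ys], axis=1).reshape(occ.n_times, occ.n_animals, 2)
    return TrajectorySet(list(occ.animal_ids), np.arange(occ.n_times), pos)
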