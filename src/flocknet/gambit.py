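"""Gambit-of-the-group baseline: distance-window association networks.

The gambit records an association whenever two animals are in the "same
place at the same time".  Here that is operationalised per observation
window: a pair is affiliated in a window iff their Euclidean separation is
within d metres for at least beta_pct per cent of the window's raw time
points.  With every animal observed in every window, the simple-ratio
index applies: edge weight = affiliated windows / total windows.

This heuristic has no null model — its output depends strongly on the
choice of d, which is the motivation for the significance test in
:mod:`flocknet.affiliation_test`.  A sweep helper exposes that sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import AffiliationNetwork
from .trajectories import TrajectorySet

__all__ = ["GambitConfig", "gambit_network", "gambit_sweep", "sweep_report"]


@dataclass
class GambitConfig:
    """Association definition: distance d (m), window fraction, window length.

    ``beta_pct`` is the required percentage of a window's time points (in
    [0, 100]) during which the pair must be within ``d`` metres
    (closed, <= d).  ``window_length`` counts raw time points per
    non-overlapping window; the trailing partial window is dropped.
    """

    d: float
    beta_pct: float = 5.0
    window_length: int = 1

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        if not 0.0 <= self.beta_pct <= 100.0:
            raise ValueError("beta_pct must lie in [0, 100]")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")


def _window_affiliations(ts: TrajectorySet, cfg: GambitConfig) -> np.ndarray:
    """Count, per pair, the windows in which the pair is affiliated."""
    H_raw, N = ts.n_times, ts.n_animals
    L = cfg.window_length
    if H_raw < L:
        raise ValueError("window_length exceeds number of raw time points")
    W = H_raw // L
    pos = ts.positions[: W * L].reshape(W, L, N, 2)
    counts = np.zeros((N, N))
    need = cfg.beta_pct / 100.0
    for w in range(W):
        diff = pos[w, :, :, None, :] - pos[w, :, None, :, :]
        close = np.linalg.norm(diff, axis=3) <= cfg.d  # (L, N, N)
        frac = close.mean(axis=0)
        counts += frac >= need
    return counts, W


def gambit_network(ts: TrajectorySet, cfg: GambitConfig) -> AffiliationNetwork:
    """Simple-ratio weighted association network under the gambit definition."""
    counts, W = _window_affiliations(ts, cfg)
    weights = counts / W
    np.fill_diagonal(weights, 0.0)
    return AffiliationNetwork(
        list(ts.animal_ids),
        weights,
        kind="weighted",
        metadata={"d": cfg.d, "beta_pct": cfg.beta_pct,
                  "window_length": cfg.window_length, "n_windows": W},
    )


def gambit_sweep(
    ts: TrajectorySet, cfg_base: GambitConfig, d_values
) -> list[AffiliationNetwork]:
    """One gambit network per distance threshold, over identical windows."""
    d_values = list(d_values)
    if not d_values:
        raise ValueError("d_values must be nonempty")
    return [
        gambit_network(
            ts,
            GambitConfig(
                d=d, beta_pct=cfg_base.beta_pct, window_length=cfg_base.window_length
            ),
        )
        for d in d_values
    ]


def sweep_report(networks: list[AffiliationNetwork], labels=None) -> pd.DataFrame:
    """Tabulate edge counts (and two-group connectivity, if labelled) per d."""
    from .networks import connectivity_stats

    rows = []
    for net in networks:
        row = {"d": net.metadata.get("d"), "edges": net.edge_count()}
        if labels is not None:
            cs = connectivity_stats(net, labels)
            row.update(
                connectivity_within_1=cs.within_connectivity[0],
                connectivity_within_2=cs.within_connectivity[1],
                connectivity_between=cs.between_connectivity,
            )
        rows.append(row)
    return pd.DataFrame(rows)
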