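"""Affiliation networks assembled from pairwise significance results.

Binary networks place an edge wherever the co-occurrence test rejects
independence.  Two weighted constructions are provided: the *baseline*
weight (e_obs - beta) / (H - beta), which discounts the co-occurrences
attributable to chance under the null, and *segment averaging*, the mean of
per-segment binary networks over a partition of the observation period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .affiliation_test import PairTestResult, test_all_pairs
from .movement_models import fit_categorical, fit_markov, MarkovModel
from .partition import OccupancySequences

__all__ = [
    "AffiliationNetwork",
    "binary_network",
    "baseline_weight",
    "baseline_network",
    "segment_averaged_network",
    "prune",
    "ConnectivityStats",
    "connectivity_stats",
]


@dataclass
class AffiliationNetwork:
    """Symmetric weighted adjacency over animals, with provenance metadata."""

    nodes: list
    weights: np.ndarray
    kind: str = "weighted"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        N = len(self.nodes)
        if self.weights.shape != (N, N):
            raise ValueError("weights must be N x N")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.kind == "binary" and not np.isin(self.weights, (0.0, 1.0)).all():
            raise ValueError("binary network weights must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def to_edgelist(self, path=None) -> pd.DataFrame:
        """Tidy edge list (source, target, weight) over nonzero edges."""
        iu, ju = np.triu_indices(self.n_nodes, 1)
        mask = self.weights[iu, ju] != 0
        df = pd.DataFrame(
            {
                "source": [self.nodes[i] for i in iu[mask]],
                "target": [self.nodes[j] for j in ju[mask]],
                "weight": self.weights[iu[mask], ju[mask]],
            }
        )
        if path is not None:
            df.to_csv(path, index=False)
        return df

    @classmethod
    def from_edgelist(cls, df_or_path, nodes: list, kind: str = "weighted"):
        df = (
            df_or_path
            if isinstance(df_or_path, pd.DataFrame)
            else pd.read_csv(df_or_path)
        )
        index = {v: i for i, v in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for _, row in df.iterrows():
            i, j = index[row["source"]], index[row["target"]]
            W[i, j] = W[j, i] = row["weight"]
        return cls(list(nodes), W, kind=kind)

    def to_networkx(self, labels: dict | None = None) -> nx.Graph:
        g = nx.Graph()
        for v in self.nodes:
            g.add_node(v, **({"group": labels[v]} if labels else {}))
        iu, ju = np.triu_indices(self.n_nodes, 1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0:
                g.add_edge(self.nodes[i], self.nodes[j], weight=float(w))
        return g

    def to_graphml(self, path, labels: dict | None = None) -> None:
        nx.write_graphml(self.to_networkx(labels), path)

    @classmethod
    def from_graphml(cls, path, kind: str = "weighted"):
        g = nx.read_graphml(path)
        nodes = list(g.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for u, v, data in g.edges(data=True):
            W[index[u], index[v]] = W[index[v], index[u]] = data.get("weight", 1.0)
        return cls(nodes, W, kind=kind)


def _results_to_matrix(results: list[PairTestResult], nodes: list, value):
    index = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    seen = set()
    for r in results:
        i, j = index[r.pair[0]], index[r.pair[1]]
        W[i, j] = W[j, i] = value(r)
        seen.add(frozenset((i, j)))
    expected = len(nodes) * (len(nodes) - 1) // 2
    if len(seen) != expected:
        raise ValueError(
            f"results cover {len(seen)} pairs but {expected} are required"
        )
    return W


def binary_network(results: list[PairTestResult], nodes: list) -> AffiliationNetwork:
    """Edge (n, n') present iff the pair's null was rejected (e_obs > beta)."""
    W = _results_to_matrix(results, nodes, lambda r: float(r.reject))
    return AffiliationNetwork(list(nodes), W, kind="binary")


def baseline_weight(e_obs: int, beta: int, n_times: int) -> float:
    """Chance-discounted edge weight (e_obs - beta) / (H - beta); 0 if not significant."""
    if not 0 <= e_obs <= n_times:
        raise ValueError("e_obs must lie in 0..H")
    if not -1 <= beta <= n_times:
        raise ValueError("beta must lie in -1..H")
    if beta >= e_obs:
        return 0.0
    return (e_obs - beta) / (n_times - beta)


def baseline_network(results: list[PairTestResult], nodes: list) -> AffiliationNetwork:
    """Weighted network with chance-discounted baseline edge weights."""
    W = _results_to_matrix(
        results, nodes, lambda r: baseline_weight(r.e_obs, r.beta, r.n_times)
    )
    return AffiliationNetwork(list(nodes), W, kind="weighted")


def _fit(occ: OccupancySequences, model_kind: str, pooled: bool):
    if model_kind == "categorical":
        if pooled:
            return fit_categorical(occ, "pooled")
        return [fit_categorical(occ, n) for n in range(occ.n_animals)]
    if model_kind == "markov":
        if pooled:
            return fit_markov(occ, "pooled")
        return [fit_markov(occ, n) for n in range(occ.n_animals)]
    raise ValueError(f"unknown model_kind {model_kind!r}")


def _pooled_counts(segments: list[OccupancySequences]) -> np.ndarray:
    D = segments[0].n_cells
    num = np.zeros((D, D))
    for occ in segments:
        for n in range(occ.n_animals):
            seq = occ.indices[:, n]
            np.add.at(num, (seq[1:], seq[:-1]), 1.0)
    return num


def segment_averaged_network(
    segments: list[OccupancySequences],
    alpha: float = 0.005,
    model_kind: str = "categorical",
    train: str = "global",
) -> AffiliationNetwork:
    """Mean of per-segment binary networks.

    ``train='global'`` fits one movement model from all segments (pooled
    over animals; Markov transition counts are summed per segment so no
    spurious cross-segment transition enters), reusing it for every
    segment's test; ``train='per_segment'`` refits on each segment.  Each
    Markov segment test starts from that segment's own initial cells.
    """
    if not segments:
        raise ValueError("at least one segment is required")
    ids0 = list(segments[0].animal_ids)
    for occ in segments[1:]:
        if list(occ.animal_ids) != ids0 or occ.n_cells != segments[0].n_cells:
            raise ValueError("segments must share animals and partition")
    if train not in ("global", "per_segment"):
        raise ValueError("train must be 'global' or 'per_segment'")

    global_model = None
    if train == "global":
        if model_kind == "categorical":
            stacked = OccupancySequences(
                np.vstack([occ.indices for occ in segments]),
                segments[0].n_cells,
                ids0,
            )
            global_model = fit_categorical(stacked, "pooled")
        else:
            num = _pooled_counts(segments)
            departures = num.sum(axis=0)
            undefined = departures == 0
            D = segments[0].n_cells
            T = np.full((D, D), np.nan)
            T[:, ~undefined] = num[:, ~undefined] / departures[~undefined]
            global_model = MarkovModel(T=T, undefined=undefined, pooled=True)

    mean_W = np.zeros((len(ids0), len(ids0)))
    for occ in segments:
        if train == "per_segment":
            model = _fit(occ, model_kind, pooled=True)
        elif model_kind == "markov":
            # shared transition matrix, this segment's initial cells
            p0 = np.zeros((occ.n_cells, occ.n_animals))
            p0[occ.indices[0], np.arange(occ.n_animals)] = 1.0
            model = MarkovModel(
                T=global_model.T,
                p0_by_animal=p0,
                undefined=global_model.undefined,
                pooled=True,
            )
        else:
            model = global_model
        results = test_all_pairs(occ, model, alpha, model_kind)
        mean_W += binary_network(results, ids0).weights
    mean_W /= len(segments)
    return AffiliationNetwork(
        ids0,
        mean_W,
        kind="weighted",
        metadata={"alpha": alpha, "model_kind": model_kind,
                  "segments": len(segments), "train": train},
    )


def prune(net: AffiliationNetwork, threshold: float = 0.1) -> AffiliationNetwork:
    """Zero out edges with weight strictly below ``threshold``.

    For reporting and display only — never applied before statistics.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    W = np.where(net.weights < threshold, 0.0, net.weights)
    meta = dict(net.metadata, prune_threshold=threshold)
    return AffiliationNetwork(list(net.nodes), W, kind=net.kind, metadata=meta)


@dataclass
class ConnectivityStats:
    """Six two-group summary statistics of an affiliation network.

    Connectivity level = proportion of realised (nonzero) edges among
    possible edges in the block; mean weight = mean over the block's
    nonzero edges, reported as 0 (and flagged) when the block has none.
    """

    groups: tuple
    within_connectivity: tuple  # (group 1, group 2)
    between_connectivity: float
    within_mean_weight: tuple
    between_mean_weight: float
    empty_blocks: tuple = ()

    def as_array(self) -> np.ndarray:
        """Order: conn within-1, within-2, between; mean w within-1, within-2, between."""
        return np.array(
            [
                self.within_connectivity[0],
                self.within_connectivity[1],
                self.between_connectivity,
                self.within_mean_weight[0],
                self.within_mean_weight[1],
                self.between_mean_weight,
            ]
        )

    STAT_NAMES = (
        "connectivity_within_1",
        "connectivity_within_2",
        "connectivity_between",
        "mean_weight_within_1",
        "mean_weight_within_2",
        "mean_weight_between",
    )


def _block_stats(W: np.ndarray, rows: np.ndarray, cols: np.ndarray, within: bool):
    sub = W[np.ix_(rows, cols)]
    if within:
        iu, ju = np.triu_indices(len(rows), 1)
        vals = sub[iu, ju]
    else:
        vals = sub.ravel()
    nonzero = vals[vals != 0]
    connectivity = nonzero.size / vals.size if vals.size else 0.0
    mean_w = float(nonzero.mean()) if nonzero.size else 0.0
    return connectivity, mean_w, nonzero.size == 0


def connectivity_stats(net: AffiliationNetwork, labels) -> ConnectivityStats:
    """Within/between connectivity levels and mean nonzero edge weights.

    ``labels`` maps each node (dict) or position (sequence) to one of
    exactly two group labels; groups are ordered by sorted label.
    """
    if isinstance(labels, dict):
        lab = np.asarray([labels[v] for v in net.nodes])
    else:
        lab = np.asarray(list(labels))
    groups = sorted(set(lab.tolist()))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    g1 = np.nonzero(lab == groups[0])[0]
    g2 = np.nonzero(lab == groups[1])[0]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 members")

    c1, w1, e1 = _block_stats(net.weights, g1, g1, within=True)
    c2, w2, e2 = _block_stats(net.weights, g2, g2, within=True)
    cb, wb, eb = _block_stats(net.weights, g1, g2, within=False)
    empty = tuple(
        name
        for name, flag in zip(
            ("within_1", "within_2", "between"), (e1, e2, eb)
        )
        if flag
    )
    return ConnectivityStats(
        groups=tuple(groups),
        within_connectivity=(c1, c2),
        between_connectivity=cb,
        within_mean_weight=(w1, w2),
        between_mean_weight=wb,
        empty_blocks=empty,
    )
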