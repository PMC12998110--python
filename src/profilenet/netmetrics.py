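"""Centrality indices and bootstrap stability for estimated networks.

Strength is the unsigned sum of a node's edge weights, expected influence
the signed sum.  Closeness and betweenness are computed on the graph of
nonzero-|weight| edges with distance 1/|weight|; closeness is the harmonic
variant (mean of inverse shortest-path distances) so that disconnected
graphs remain well defined.  Each index is also reported z-standardized
across nodes.

Stability machinery follows common practice for cross-sectional network
analysis: nonparametric bootstrap (resample rows, refit, percentile CIs for
every edge) and the case-dropping bootstrap behind the correlation-stability
(CS) coefficient — the largest fraction of cases that can be dropped while
at least 95% of refits keep a Pearson correlation of at least 0.7 with the
full-sample centrality ordering (≥ 0.25 acceptable, ≥ 0.5 strong).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ising import BinaryMatrix, IsingNetwork, fit_elasso

__all__ = [
    "CentralityTable",
    "centrality",
    "EdgeStability",
    "bootstrap_edges",
    "CSResult",
    "cs_coefficient",
    "compare_top_nodes",
]

CS_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))


@dataclass
class CentralityTable:
    table: pd.DataFrame  # index node; raw + z columns per index
    degenerate: bool = False  # all-zero network: z undefined

    def raw(self, index: str) -> pd.Series:
        return self.table[index]

    def z(self, index: str) -> pd.Series:
        return self.table[f"{index}_z"]

    def top(self, k: int, index: str = "strength") -> list[str]:
        if k > len(self.table):
            raise ValueError("k exceeds the number of nodes")
        return list(self.table[index].sort_values(ascending=False).index[:k])


def _weighted_graph(network: IsingNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(network.labels)
    for a, b, w in network.edge_list():
        G.add_edge(a, b, weight=abs(w), distance=1.0 / abs(w))
    return G


def centrality(network: IsingNetwork) -> CentralityTable:
    """Strength, expected influence, harmonic closeness, betweenness (+z)."""
    if network.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    W = network.weights
    P = network.n_nodes
    strength = np.abs(W).sum(axis=1)
    ei = W.sum(axis=1)
    G = _weighted_graph(network)
    harm = nx.harmonic_centrality(G, distance="distance")
    closeness = np.array([harm[l] / (P - 1) for l in network.labels])
    btw = nx.betweenness_centrality(G, weight="distance", normalized=True)
    betweenness = np.array([btw[l] for l in network.labels])

    table = pd.DataFrame(
        {
            "strength": strength,
            "expected_influence": ei,
            "closeness": closeness,
            "betweenness": betweenness,
        },
        index=list(network.labels),
    )
    degenerate = bool(np.all(W == 0))
    for col in list(table.columns):
        sd = table[col].std(ddof=1)
        if sd > 0:
            table[f"{col}_z"] = (table[col] - table[col].mean()) / sd
        else:
            # no variance across nodes: every node sits at the mean
            table[f"{col}_z"] = np.nan if degenerate else 0.0
    return CentralityTable(table, degenerate=degenerate)


# ---------------------------------------------------------------------------
# nonparametric bootstrap of edge weights
# ---------------------------------------------------------------------------

@dataclass
class EdgeStability:
    edges: pd.DataFrame  # node_i, node_j, estimate, ci_lower, ci_upper
    B: int
    n_refit_failures: int
    settings: dict = field(default_factory=dict)


def bootstrap_edges(
    binary: BinaryMatrix,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.25,
    rule: str = "and",
    n_lambda: int = 100,
    probability: float = 0.95,
) -> EdgeStability:
    """Row-resampling bootstrap of eLASSO edge weights with percentile CIs."""
    full = fit_elasso(binary, gamma=gamma, rule=rule, n_lambda=n_lambda)
    P = binary.n_nodes
    iu = np.triu_indices(P, k=1)
    rng = np.random.default_rng(seed)
    boots = np.zeros((B, len(iu[0])))
    failures = 0
    b = 0
    attempts = 0
    while b < B:
        attempts += 1
        if attempts > 10 * B:
            raise RuntimeError("too many bootstrap refit failures")
        idx = rng.integers(binary.n, size=binary.n)
        sub = binary.values[idx]
        means = sub.mean(axis=0)
        if np.any((means == 0) | (means == 1)):
            failures += 1  # resample: constant column, fit undefined
            continue
        net_b = fit_elasso(
            BinaryMatrix(sub, binary.labels), gamma=gamma, rule=rule,
            n_lambda=n_lambda,
        )
        boots[b] = net_b.weights[iu]
        b += 1
    alpha = (1.0 - probability) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    edges = pd.DataFrame(
        {
            "node_i": [binary.labels[i] for i in iu[0]],
            "node_j": [binary.labels[j] for j in iu[1]],
            "estimate": full.weights[iu],
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    return EdgeStability(
        edges=edges,
        B=B,
        n_refit_failures=failures,
        settings={"gamma": gamma, "rule": rule, "probability": probability,
                  "n_lambda": n_lambda},
    )


# ---------------------------------------------------------------------------
# case-dropping bootstrap: CS coefficient
# ---------------------------------------------------------------------------

@dataclass
class CSResult:
    cs: float
    index: str
    per_fraction: pd.DataFrame  # drop_fraction, n_iter, prop_ok
    settings: dict = field(default_factory=dict)


def _index_values(net: IsingNetwork, index: str) -> np.ndarray:
    W = net.weights
    if index == "strength":
        return np.abs(W).sum(axis=1)
    if index in ("expected_influence", "ei"):
        return W.sum(axis=1)
    raise ValueError("index must be 'strength' or 'expected_influence'")


def cs_coefficient(
    binary: BinaryMatrix,
    index: str = "strength",
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.25,
    rule: str = "and",
    n_lambda: int = 100,
    correlation_threshold: float = 0.7,
    probability: float = 0.95,
    drop_grid: Sequence[float] = CS_DROP_GRID,
) -> CSResult:
    """Correlation-stability coefficient of a centrality index.

    ``B`` case-dropping iterations are spread evenly over the drop-fraction
    grid.  An iteration succeeds when the Pearson correlation between the
    subsample and full-sample index values is at least
    ``correlation_threshold``; iterations whose subsample network is
    degenerate (empty, or correlation undefined) count as failures.  The CS
    value is the largest grid fraction up to which every smaller fraction
    also meets the ≥ ``probability`` success criterion.
    """
    if binary.n < 50:
        raise ValueError("case-dropping bootstrap needs n >= 50")
    full = fit_elasso(binary, gamma=gamma, rule=rule, n_lambda=n_lambda)
    ref = _index_values(full, index)
    rng = np.random.default_rng(seed)
    grid = list(drop_grid)
    per_frac = max(1, B // len(grid))
    rows = []
    for frac in grid:
        keep = int(round((1.0 - frac) * binary.n))
        ok = 0
        for _ in range(per_frac):
            idx = rng.choice(binary.n, size=keep, replace=False)
            sub = binary.values[idx]
            means = sub.mean(axis=0)
            if np.any((means == 0) | (means == 1)):
                continue  # failure
            net_s = fit_elasso(
                BinaryMatrix(sub, binary.labels), gamma=gamma, rule=rule,
                n_lambda=n_lambda,
            )
            vals = _index_values(net_s, index)
            if np.std(vals) == 0 or np.std(ref) == 0:
                continue  # failure: correlation undefined
            r = np.corrcoef(vals, ref)[0, 1]
            if r >= correlation_threshold:
                ok += 1
        rows.append(
            {"drop_fraction": frac, "n_iter": per_frac, "prop_ok": ok / per_frac}
        )
    per_fraction = pd.DataFrame(rows)
    cs = 0.0
    for _, row in per_fraction.iterrows():
        if row["prop_ok"] >= probability:
            cs = row["drop_fraction"]
        else:
            break
    return CSResult(
        cs=float(cs),
        index=index,
        per_fraction=per_fraction,
        settings={
            "B": B,
            "per_fraction": per_frac,
            "correlation_threshold": correlation_threshold,
            "probability": probability,
            "gamma": gamma,
            "rule": rule,
        },
    )


def compare_top_nodes(
    table_a: CentralityTable,
    table_b: CentralityTable,
    k: int = 3,
    index: str = "strength",
    named_node: str | None = None,
) -> dict:
    """Top-k overlap between two centrality tables (same node set)."""
    if set(table_a.table.index) != set(table_b.table.index):
        raise ValueError("tables must share the same node set")
    top_a = set(table_a.top(k, index))
    top_b = set(table_b.top(k, index))
    overlap = top_a & top_b
    out = {
        "top_a": sorted(top_a),
        "top_b": sorted(top_b),
        "overlap": sorted(overlap),
        "overlap_size": len(overlap),
    }
    if named_node is not None:
        out["named_node_in_both"] = named_node in top_a and named_node in top_b
    return out
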