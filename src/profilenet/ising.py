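"""Ising network estimation for dichotomized questionnaire items.

The Ising model over binary responses x in {0,1}^P is

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} β_ij x_i x_j )

with node thresholds τ and symmetric pairwise interactions β.  Networks are
estimated by eLASSO: for every node an L1-penalized logistic regression of
that node on all others, the penalty chosen per node by the extended BIC

    EBIC = -2·loglik + J·ln(n) + 2γ·J·ln(P-1)

where J counts the selected neighbours, and the two directed estimates of
each pair combined by an AND (default) or OR rule with the edge weight set
to the mean of the two coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._logistic import lambda_max, logistic_lasso_path
from .datasets import ResponseDataset

__all__ = [
    "BinaryMatrix",
    "IsingNetwork",
    "IsingModel",
    "IsingResults",
    "dichotomize",
    "fit_elasso",
    "write_network",
    "read_network",
]


@dataclass
class BinaryMatrix:
    """n × P binary (0/1) data with node labels."""

    values: np.ndarray
    labels: tuple[str, ...]
    dropped_constant: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.labels = tuple(self.labels)
        if self.values.ndim != 2:
            raise ValueError("binary matrix must be 2-D")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")
        uniq = np.unique(self.values)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("entries must be 0/1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class IsingNetwork:
    """Thresholds τ, symmetric edge weights β and estimation metadata."""

    thresholds: np.ndarray
    weights: np.ndarray
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(self.labels)
        P = len(self.labels)
        if self.thresholds.shape != (P,) or self.weights.shape != (P, P):
            raise ValueError("shape mismatch between labels, thresholds, weights")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weight matrix must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((self.labels[i], self.labels[j], float(w)))
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edge_list())


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

def dichotomize(
    data: ResponseDataset,
    rule: str = "midpoint",
    threshold: int = 4,
    drop_constant: bool = True,
) -> BinaryMatrix:
    """Collapse Likert responses to 0/1 for the Ising model.

    ``midpoint`` (default): response >= ``threshold`` (default 4, i.e. the
    "confident"/"completely confident" end of a 5-point scale) becomes 1.
    ``median``: per-item median split, strictly-greater-than-median becomes 1.

    Columns that end up constant are excluded from the matrix (nodewise
    logistic fits are undefined for them) and recorded in
    ``dropped_constant``.
    """
    X = data.item_matrix()
    if rule == "midpoint":
        B = (X >= threshold).astype(np.int8)
    elif rule == "median":
        med = np.median(X, axis=0)
        B = (X > med).astype(np.int8)
    else:
        raise ValueError(f"unknown dichotomization rule: {rule!r}")

    labels = list(data.item_labels)
    means = B.mean(axis=0)
    const = (means == 0.0) | (means == 1.0)
    dropped: tuple[str, ...] = ()
    if drop_constant and const.any():
        dropped = tuple(np.asarray(labels)[const])
        B = B[:, ~const]
        labels = [l for l, c in zip(labels, const) if not c]
    return BinaryMatrix(B, tuple(labels), dropped_constant=dropped)


# ---------------------------------------------------------------------------
# eLASSO estimation
# ---------------------------------------------------------------------------

def combine_directed(directed: np.ndarray, rule: str) -> np.ndarray:
    """Symmetrize the directed nodewise estimates into edge weights.

    AND keeps a pair only when both directions selected it; OR keeps it when
    either did.  The weight is the mean of the two directed coefficients in
    both cases (so an OR edge selected in one direction is halved).
    """
    both = (directed != 0) & (directed.T != 0)
    either = (directed != 0) | (directed.T != 0)
    keep = both if rule == "and" else either
    W = np.where(keep, (directed + directed.T) / 2.0, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def fit_elasso(
    binary: BinaryMatrix,
    gamma: float = 0.25,
    rule: str = "and",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-5,
) -> IsingNetwork:
    """Estimate an Ising network by nodewise EBIC-tuned lasso logistic fits.

    Per node the penalty path runs from the smallest lambda producing an
    empty model down to ``lambda_min_ratio`` times that value on a log grid
    (``n_lambda`` points); the path model minimizing the EBIC is retained.
    Ties prefer the sparser (larger-penalty) model.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    X = binary.values.astype(float)
    n, P = X.shape
    if P < 2:
        raise ValueError("need at least two nodes")
    means = X.mean(axis=0)
    if np.any((means == 0) | (means == 1)):
        raise ValueError("constant columns present; dichotomize with drop_constant")

    directed = np.zeros((P, P))  # directed[i, j]: coefficient of j predicting i
    tau = np.zeros(P)
    node_info = []
    for i in range(P):
        others = [j for j in range(P) if j != i]
        Xi = X[:, others]
        y = X[:, i]
        lam_max = lambda_max(Xi, y)
        if lam_max <= 0:
            lam_max = 1e-3
        lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
        coefs, intercepts, logliks, separated = logistic_lasso_path(
            Xi, y, lams, tol=tol
        )
        J = (coefs != 0).sum(axis=1)
        ebic = -2.0 * logliks + J * np.log(n) + 2.0 * gamma * J * np.log(P - 1)
        best = int(np.argmin(ebic))
        directed[i, others] = coefs[best]
        tau[i] = intercepts[best]
        node_info.append(
            {
                "node": binary.labels[i],
                "lambda": float(lams[best]),
                "n_neighbours": int(J[best]),
                "ebic": float(ebic[best]),
                "separated": bool(separated),
            }
        )

    W = combine_directed(directed, rule)
    meta = {
        "estimator": "eLASSO",
        "gamma": gamma,
        "rule": rule,
        "n": n,
        "n_lambda": n_lambda,
        "lambda_min_ratio": lambda_min_ratio,
        "nodes": node_info,
        "dropped_constant": list(binary.dropped_constant),
    }
    return IsingNetwork(tau, W, binary.labels, meta)


class IsingModel:
    """Model object for Ising network estimation from binary data."""

    def __init__(self, binary: BinaryMatrix):
        self.binary = binary

    @classmethod
    def from_responses(
        cls, data: ResponseDataset, rule: str = "midpoint", threshold: int = 4
    ) -> "IsingModel":
        return cls(dichotomize(data, rule=rule, threshold=threshold))

    def fit(
        self,
        gamma: float = 0.25,
        rule: str = "and",
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
    ) -> "IsingResults":
        net = fit_elasso(
            self.binary,
            gamma=gamma,
            rule=rule,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
        )
        return IsingResults(self, net)


@dataclass
class IsingResults:
    model: IsingModel
    network: IsingNetwork

    @property
    def thresholds(self) -> np.ndarray:
        return self.network.thresholds

    @property
    def weights(self) -> np.ndarray:
        return self.network.weights

    def summary(self) -> str:
        net = self.network
        lines = [
            "Ising network (eLASSO)",
            f"  nodes: {net.n_nodes}   edges: {net.n_edges}   "
            f"n: {net.meta.get('n')}   gamma: {net.meta.get('gamma')}   "
            f"rule: {net.meta.get('rule')}",
            f"  mean |edge weight|: "
            f"{np.mean([abs(w) for *_, w in net.edge_list()]) if net.n_edges else 0.0:.4f}",
            "  node  threshold  degree",
        ]
        deg = (net.weights != 0).sum(axis=0)
        for i, lab in enumerate(net.labels):
            lines.append(f"  {lab:>6} {net.thresholds[i]:>9.3f} {deg[i]:>7d}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# network IO: lossless plain-text edge-list format
# ---------------------------------------------------------------------------

_HEADER = "# profilenet ising network v1"


def write_network(network: IsingNetwork, path: str | Path) -> None:
    """Write a network as a plain-text node/edge list (lossless round trip)."""
    import json

    lines = [_HEADER]
    lines.append("meta\t" + json.dumps(network.meta))
    for lab, t in zip(network.labels, network.thresholds):
        lines.append(f"node\t{lab}\t{float(t)!r}")
    for a, b, w in network.edge_list():
        lines.append(f"edge\t{a}\t{b}\t{float(w)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> IsingNetwork:
    import json

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _HEADER:
        raise ValueError(f"{path}: line 1: not a profilenet network file")
    meta: dict = {}
    labels: list[str] = []
    taus: list[float] = []
    edges: list[tuple[str, str, float]] = []
    for no, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            if parts[0] == "meta":
                meta = json.loads(parts[1])
            elif parts[0] == "node":
                labels.append(parts[1])
                taus.append(float(parts[2]))
            elif parts[0] == "edge":
                edges.append((parts[1], parts[2], float(parts[3])))
            else:
                raise ValueError(f"unknown record type {parts[0]!r}")
        except (IndexError, ValueError, KeyError) as exc:
            raise ValueError(f"{path}: line {no}: {exc}") from exc
    idx = {lab: i for i, lab in enumerate(labels)}
    P = len(labels)
    W = np.zeros((P, P))
    for a, b, w in edges:
        if a not in idx or b not in idx:
            raise ValueError(f"{path}: edge references unknown node {a!r}/{b!r}")
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w
    return IsingNetwork(np.array(taus), W, tuple(labels), meta)


def write_edgelist_csv(network: IsingNetwork, edges_path, thresholds_path) -> None:
    """CSV exports (edges + thresholds) for downstream tools; not lossless."""
    import pandas as pd

    pd.DataFrame(
        network.edge_list(), columns=["node_i", "node_j", "weight"]
    ).to_csv(edges_path, index=False)
    pd.DataFrame(
        {"node": network.labels, "threshold": network.thresholds}
    ).to_csv(thresholds_path, index=False)
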