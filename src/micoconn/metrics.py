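"""Weighted network measures for structural connectomes.

The five measures the developmental analysis tracks:

* **strength** — sum of a node's edge weights; reported as the mean.
* **global efficiency** — mean inverse weighted shortest-path length
  over ordered node pairs (disconnected pairs contribute 0), with edge
  length = 1/weight.
* **local efficiency** — global efficiency of the subgraph induced by a
  node's neighbours (node excluded); 0 with fewer than 2 neighbours.
* **clustering coefficient** — Onnela's geometric-mean triangle
  intensity, weights normalized by the graph's maximum weight.
* **modularity** — Newman's spectral community detection (leading
  eigenvector bisection with Kernighan-Lin style single-node
  refinement), resolution parameter gamma.

All functions accept a :class:`~micoconn.connectome.Connectome` or a
plain symmetric non-negative matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome import Connectome, connection_density, subnetwork_extract
from .parcellation import NetworkAssignment

__all__ = [
    "MetricConfig",
    "strength",
    "mean_strength",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "modularity",
    "compute_metric_table",
    "local_efficiency_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricConfig:
    """Knobs of the graph measures.

    gamma : modularity resolution (>0, default 1).
    length_transform : rule converting weights to path lengths for the
        efficiency measures; only 'reciprocal' (length = 1/w) is defined.
    """

    gamma: float = 1.0
    length_transform: str = "reciprocal"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.length_transform != "reciprocal":
            raise ValueError("only the reciprocal length transform is supported")


DEFAULT_METRIC_CONFIG = MetricConfig()


def _as_matrix(connectome) -> np.ndarray:
    w = connectome.matrix if isinstance(connectome, Connectome) else np.asarray(
        connectome, dtype=float
    )
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square connectivity matrix")
    return w


def strength(connectome) -> np.ndarray:
    """Nodal strength s_i = sum_j w_ij."""
    return _as_matrix(connectome).sum(axis=1)


def mean_strength(connectome) -> float:
    return float(strength(connectome).mean())


def _inverse_distance_matrix(w: np.ndarray) -> np.ndarray:
    """1/d_ij from weighted Dijkstra with length = 1/w; 0 where unreachable."""
    n = w.shape[0]
    i, j = np.nonzero(w)
    lengths = csr_matrix((1.0 / w[i, j], (i, j)), shape=(n, n))
    d = dijkstra(lengths, directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(connectome, config: MetricConfig = DEFAULT_METRIC_CONFIG) -> float:
    """Mean of 1/d_ij over ordered node pairs (1/inf = 0)."""
    w = _as_matrix(connectome)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    inv = _inverse_distance_matrix(w)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(
    connectome, node: int, config: MetricConfig = DEFAULT_METRIC_CONFIG
) -> float:
    """Global efficiency of the neighbourhood subgraph of ``node``."""
    w = _as_matrix(connectome)
    if not 0 <= node < w.shape[0]:
        raise ValueError(f"node {node} not in graph")
    nbrs = np.flatnonzero(w[node] > 0)
    if nbrs.size < 2:
        return 0.0
    return global_efficiency(w[np.ix_(nbrs, nbrs)], config)


def clustering_coefficient(connectome) -> np.ndarray:
    """Onnela per-node weighted clustering, weights scaled by max weight."""
    w = _as_matrix(connectome).copy()
    n = w.shape[0]
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    cube = np.cbrt(w / wmax)
    cyc3 = np.diag(cube @ cube @ cube)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.zeros(n)
    mask = denom > 0
    c[mask] = cyc3[mask] / denom[mask]
    return c


def _refine_split(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Greedy single-node sweeps: flip the best node while Q improves."""
    s = s.copy()
    Bs = Bg @ s
    while True:
        gains = -4.0 * s * Bs + 4.0 * np.diag(Bg)
        j = int(np.argmax(gains))
        if gains[j] <= 1e-12:
            return s
        s[j] = -s[j]
        Bs += 2.0 * s[j] * Bg[:, j]


def _partition_quality(w: np.ndarray, comms: np.ndarray, gamma: float) -> float:
    v = w.sum()
    s = w.sum(axis=1)
    B = w - gamma * np.outer(s, s) / v
    q = 0.0
    for c in np.unique(comms):
        idx = comms == c
        q += B[np.ix_(idx, idx)].sum()
    return q / v


def modularity(
    connectome, config: MetricConfig = DEFAULT_METRIC_CONFIG, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Newman spectral modularity: returns (Q, community label per node).

    Recursive leading-eigenvector bisection of the (generalized)
    modularity matrix; nodes with zero eigenvector entries join the
    positive block; each split is polished by single-node moves and
    accepted only if it increases Q. Fully deterministic — the seed is
    accepted for interface symmetry with stochastic stages.
    """
    w = _as_matrix(connectome)
    v = w.sum()
    if v <= 0:
        raise ValueError("modularity needs positive total weight")
    n = w.shape[0]
    s_deg = w.sum(axis=1)
    B = w - config.gamma * np.outer(s_deg, s_deg) / v

    comms = np.zeros(n, dtype=int)
    next_label = [1]

    def split(nodes: np.ndarray) -> None:
        if nodes.size < 2:
            return
        Bsub = B[np.ix_(nodes, nodes)]
        Bg = Bsub - np.diag(Bsub.sum(axis=1))
        vals, vecs = np.linalg.eigh(Bg)
        lead = vecs[:, -1]
        if vals[-1] <= 1e-12:
            return
        s = np.where(lead >= 0, 1.0, -1.0)  # ties to the positive block
        s = _refine_split(Bg, s)
        dq = s @ Bg @ s / (2.0 * v)
        if dq <= 1e-12 or np.all(s == s[0]):
            return
        neg = nodes[s < 0]
        pos = nodes[s > 0]
        comms[neg] = next_label[0]
        next_label[0] += 1
        split(pos)
        split(neg)

    split(np.arange(n))
    q = _partition_quality(w, comms, config.gamma)
    return float(q), comms


_SCALAR_METRICS = ("modularity", "global_efficiency", "clustering", "mean_strength", "local_efficiency")


def _scalar_metrics(conn: Connectome, config: MetricConfig) -> dict[str, float]:
    w = conn.matrix
    n = w.shape[0]
    out: dict[str, float] = {}
    if n < 2 or w.sum() == 0:
        return {m: np.nan for m in _SCALAR_METRICS} | {"density": np.nan}
    out["modularity"] = modularity(conn, config)[0]
    out["global_efficiency"] = global_efficiency(conn, config)
    out["clustering"] = float(clustering_coefficient(conn).mean())
    out["mean_strength"] = mean_strength(conn)
    out["local_efficiency"] = float(
        np.mean([local_efficiency(w, i, config) for i in range(n)])
    )
    out["density"] = connection_density(conn)
    return out


def compute_metric_table(
    cohort,
    assignment: NetworkAssignment,
    config: MetricConfig = DEFAULT_METRIC_CONFIG,
) -> pd.DataFrame:
    """Per-subject, per-network metric table.

    One row per (subject, 'whole_brain') and per (subject, group) with
    the five weighted measures plus connection density and the subject's
    covariates. Subnetworks with fewer than 2 nodes or no edges yield
    missing values with a logged warning.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    for rec in cohort:
        base = {
            "subject": rec.id,
            "age": rec.age,
            "sex": rec.sex,
            "icv": rec.icv,
        }
        rows.append(base | {"group": "whole_brain"} | _scalar_metrics(rec.connectome, config))
        for group in assignment.groups():
            try:
                sub = subnetwork_extract(rec.connectome, assignment, group)
                vals = _scalar_metrics(sub, config)
            except ValueError:
                vals = {m: np.nan for m in _SCALAR_METRICS} | {"density": np.nan}
            if any(np.isnan(v) for v in vals.values()):
                logger.warning(
                    "subject %s group %s: metrics missing (degenerate subgraph)",
                    rec.id,
                    group,
                )
            rows.append(base | {"group": group} | vals)
    return pd.DataFrame(rows)


def local_efficiency_matrix(
    cohort,
    assignment: NetworkAssignment,
    group: str,
    config: MetricConfig = DEFAULT_METRIC_CONFIG,
) -> pd.DataFrame:
    """Subjects x nodes matrix of local efficiency within one network.

    The node-level feature matrix the age-prediction stage consumes.
    """
    rows = {}
    for rec in cohort:
        sub = subnetwork_extract(rec.connectome, assignment, group)
        rows[rec.id] = {
            f"roi_{int(lab)}": local_efficiency(sub.matrix, i, config)
            for i, lab in enumerate(sub.labels)
        }
    return pd.DataFrame.from_dict(rows, orient="index")
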