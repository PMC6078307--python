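"""Weighted node centrality for connectivity matrices.

Two indices per node, per modality:

* degree strength — weighted degree, the sum of incident edge weights
  (a binary-degree variant is available);
* betweenness centrality — unnormalized shortest-path betweenness on
  the weighted graph with edge distance 1/weight (``-log(weight)``
  selectable for weights in (0, 1]), endpoints excluded, unordered-pair
  counting, all minimal-distance paths credited fractionally.

Betweenness uses Brandes' dependency accumulation over Dijkstra
shortest paths; float distance ties are treated as equal within a
relative tolerance of 1e-12, which matters for graphs whose competing
path lengths differ only by rounding.  An exhaustive simple-path
enumeration oracle (``brute_force_betweenness``) shares the contract
for graphs of up to 9 nodes.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator, TransformerMixin

from .connectome import ConnectivityMatrix

logger = logging.getLogger(__name__)

DISTANCE_TRANSFORMS = ("inverse", "log")
_TIE_TOL = 1e-12


def _weights_of(W) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        W = W.weights
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    return W


def _edge_distances(W: np.ndarray, distance: str) -> np.ndarray:
    """Map edge weights to positive path distances; 0 means no edge."""
    if distance not in DISTANCE_TRANSFORMS:
        raise ValueError(f"distance must be one of {DISTANCE_TRANSFORMS}, "
                         f"got {distance!r}")
    D = np.full_like(W, np.inf)
    edge = W > 0
    if distance == "inverse":
        D[edge] = 1.0 / W[edge]
    else:
        if (W[edge] > 1).any():
            raise ValueError(
                "-log distance requires weights in (0, 1]; use 'inverse' "
                "for Fisher-z weights that can exceed 1")
        with np.errstate(divide="ignore"):
            D[edge] = -np.log(W[edge])
        if (D[edge] <= 0).any():
            raise ValueError(
                "-log distance requires weights strictly below 1 "
                "(zero-length edges are not supported)")
    np.fill_diagonal(D, np.inf)
    return D


def degree_strength(W, node: int | None = None, binary: bool = False):
    """Weighted degree: row sum of the weight matrix.

    With ``binary=True``, counts incident edges instead (the literal
    "number of other regions" reading).
    """
    A = _weights_of(W)
    s = (A > 0).sum(axis=1).astype(float) if binary else A.sum(axis=1)
    if node is None:
        return s
    if not (0 <= node < A.shape[0]):
        raise IndexError(f"node {node} out of range for {A.shape[0]} nodes")
    return float(s[node])


def betweenness(W, node: int | None = None, distance: str = "inverse",
                tol: float = _TIE_TOL):
    """Unnormalized weighted betweenness (Brandes accumulation).

    For each unordered pair (s, t), every node strictly inside at least
    one minimal-distance s-t path receives the fraction of such paths
    through it; disconnected pairs contribute nothing.
    """
    A = _weights_of(W)
    n = A.shape[0]
    if node is not None and not (0 <= node < n):
        raise IndexError(f"node {node} out of range for {n} nodes")
    E = _edge_distances(A, distance)
    # all-pairs shortest distances at C speed; tie handling done below
    D = dijkstra(np.where(np.isfinite(E), E, 0.0), directed=False)
    bc = np.zeros(n)
    finiteE = np.isfinite(E)
    for s in range(n):
        ds = D[s]
        reach_mask = np.isfinite(ds)
        order = np.argsort(ds)
        # predecessor matrix on the shortest-path DAG from s:
        # u precedes v iff edge (u,v) exists and d(u) + w(u,v) = d(v)
        with np.errstate(invalid="ignore"):
            via = ds[:, None] + E
            P = finiteE & (np.abs(via - ds[None, :]) <= tol * (
                1.0 + np.abs(ds[None, :]))) & (ds[:, None] < ds[None, :])
        sigma = np.zeros(n)
        sigma[s] = 1.0
        for v in order:
            if v == s or not reach_mask[v]:
                continue
            col = P[:, v]
            sigma[v] = sigma[col].sum()
        delta = np.zeros(n)
        for v in order[::-1]:
            if v == s or not reach_mask[v] or sigma[v] == 0.0:
                continue
            coeff = (1.0 + delta[v]) / sigma[v]
            col = P[:, v]
            delta[col] += sigma[col] * coeff
        delta[s] = 0.0
        bc += delta
    bc *= 0.5  # each unordered pair visited from both endpoints
    if node is None:
        return bc
    return float(bc[node])


def brute_force_betweenness(W, node: int | None = None,
                            distance: str = "inverse",
                            tol: float = _TIE_TOL):
    """Exhaustive-enumeration betweenness oracle (<= 9 nodes).

    Enumerates every simple path for every node pair, finds the
    minimal total distance, and splits credit across all tied minimal
    paths.  Same contract as :func:`betweenness`.
    """
    A = _weights_of(W)
    n = A.shape[0]
    if n > 9:
        raise ValueError(f"brute-force oracle limited to 9 nodes, got {n}")
    if node is not None and not (0 <= node < n):
        raise IndexError(f"node {node} out of range for {n} nodes")
    E = _edge_distances(A, distance)
    nbrs = [np.flatnonzero(np.isfinite(E[i])) for i in range(n)]
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths: list[tuple[float, tuple[int, ...]]] = []

        def walk(v: int, dist: float, path: tuple[int, ...]) -> None:
            if v == t:
                paths.append((dist, path))
                return
            for u in nbrs[v]:
                if u not in path:
                    walk(u, dist + E[v, u], path + (u,))

        walk(s, 0.0, (s,))
        if not paths:
            continue
        best = min(d for d, _ in paths)
        shortest = [p for d, p in paths
                    if d <= best + tol * (1.0 + abs(best))]
        credit = 1.0 / len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += credit
    if node is None:
        return bc
    return float(bc[node])


def _variable_label(metric: str, region_label: str) -> str:
    """E.g. ("betweenness", "R_NAcc") -> "B_R_NAcc"."""
    return f"{'S' if metric == 'strength' else 'B'}_{region_label}"


def metrics_table(functional: dict[str, ConnectivityMatrix] | None,
                  anatomical: dict[str, ConnectivityMatrix] | None,
                  regions: pd.DataFrame,
                  roi_labels: list[str] | None = None,
                  distance: str = "inverse",
                  binary_degree: bool = False) -> pd.DataFrame:
    """Long-format centrality table for the reporting ROIs.

    One row per (subject, modality, ROI, metric); variable labels
    follow the ``S_/B_ + hemisphere + structure`` abbreviation scheme
    (e.g. ``B_R_NAcc``).  Subjects missing a modality simply contribute
    no rows for it (logged), mirroring scan exclusions.
    """
    from .connectome import roi_indices as _roi_idx

    idx = _roi_idx(regions, roi_labels)
    labels = [regions["label"].iloc[i] for i in idx]
    rows = []
    for modality, matrices in (("functional", functional),
                               ("anatomical", anatomical)):
        if matrices is None:
            continue
        for sid, cm in matrices.items():
            if cm is None:
                logger.info("subject %s missing %s matrix; rows omitted",
                            sid, modality)
                continue
            s = degree_strength(cm, binary=binary_degree)
            b = betweenness(cm, distance=distance)
            for i, lab in zip(idx, labels):
                rows.append((sid, modality, lab,
                             _variable_label("strength", lab), float(s[i])))
                rows.append((sid, modality, lab,
                             _variable_label("betweenness", lab),
                             float(b[i])))
    return pd.DataFrame(
        rows, columns=["subject_id", "modality", "region_label",
                       "variable", "value"])


def metrics_to_block(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long metric table into the wide brain block.

    Columns are ``{func|anat}:{variable}``; index is subject_id.
    Missing modalities become NaN columns for those subjects.
    """
    t = table.copy()
    mod_code = t["modality"].map({"functional": "func", "anatomical": "anat"})
    t["column"] = mod_code + ":" + t["variable"]
    wide = t.pivot_table(index="subject_id", columns="column",
                         values="value", aggfunc="first")
    wide.columns.name = None
    return wide


class ROICentrality(BaseEstimator, TransformerMixin):
    """Transformer: list of ConnectivityMatrix -> ROI feature matrix.

    Features are strength and betweenness for each reporting ROI, in
    ``feature_names_`` order.
    """

    def __init__(self, regions=None, roi_labels=None,
                 distance: str = "inverse", binary_degree: bool = False):
        self.regions = regions
        self.roi_labels = roi_labels
        self.distance = distance
        self.binary_degree = binary_degree

    def fit(self, X, y=None):
        from .connectome import roi_indices as _roi_idx
        if self.regions is None:
            raise ValueError("regions table must be set")
        self.roi_indices_ = _roi_idx(self.regions, self.roi_labels)
        labs = [self.regions["label"].iloc[i] for i in self.roi_indices_]
        self.feature_names_ = ([f"S_{lab}" for lab in labs] +
                               [f"B_{lab}" for lab in labs])
        return self

    def transform(self, X):
        if not hasattr(self, "roi_indices_"):
            self.fit(X)
        idx = self.roi_indices_
        out = np.empty((len(X), 2 * len(idx)))
        for r, cm in enumerate(X):
            s = degree_strength(cm, binary=self.binary_degree)
            b = betweenness(cm, distance=self.distance)
            out[r, :len(idx)] = s[idx]
            out[r, len(idx):] = b[idx]
        return out
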