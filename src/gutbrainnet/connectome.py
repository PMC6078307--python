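"""Per-subject weighted connectome construction.

Functional networks: Pearson correlation of region time series,
Fisher z-transformed (atanh); edges retained only where z exceeds a
positive threshold (default 0.3, strict), with the z magnitude as the
edge weight.  Negative and sub-threshold correlations are zeroed, so
functional weights are 0 or > threshold by construction.

Anatomical networks: fiber count between two regions divided by the
sum of their volumes (streamline-density convention; ``product`` and
``mean`` normalizations are selectable).

Both yield symmetric, zero-diagonal, nonnegative weight matrices over
the same parcellation.  Centrality metrics are computed on the whole
network; the ROI list only selects which nodes are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: r-clip bound before atanh, keeps weights finite for duplicated signals
_R_CLIP = 1.0 - 1e-12

ANAT_NORMS = ("sum", "product", "mean")


@dataclass
class ConnectivityMatrix:
    """A subject-level weighted, undirected connectivity matrix."""

    subject_id: str
    modality: str                    # "functional" | "anatomical"
    weights: np.ndarray              # n_regions x n_regions, nonnegative
    labels: list[str]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.labels) != W.shape[0]:
            raise ValueError("labels must match matrix dimension")
        if not np.isfinite(W).all():
            raise ValueError("weights must be finite")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if (W < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.abs(np.diag(W)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be zero")
        if self.modality not in ("functional", "anatomical"):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.weights = W

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def functional_network(series: np.ndarray, z_threshold: float = 0.3,
                       labels: list[str] | None = None,
                       subject_id: str = "") -> ConnectivityMatrix:
    """Fisher-z thresholded correlation network from region time series.

    Parameters
    ----------
    series : array (t_points, n_regions)
        Region-level signals (already voxel-averaged).
    z_threshold : float
        Strict retention threshold on the Fisher z-transformed
        correlation; equivalently r > tanh(z_threshold).  Ties at
        exactly the threshold are removed.

    Constant-signal regions cannot be correlated; their edges are set
    to 0 with a logged warning.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim != 2:
        raise ValueError("series must be a 2-D (time x region) array")
    t, n = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 regions, got {n}")
    if t < 8:
        raise ValueError(f"need at least 8 time points, got {t}")
    if not np.isfinite(X).all():
        raise ValueError("series contains non-finite values")

    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning("constant signal in %d region(s); their edges set "
                       "to 0", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    W = np.where(z > z_threshold, z, 0.0)
    np.fill_diagonal(W, 0.0)
    if labels is None:
        labels = [str(i) for i in range(n)]
    return ConnectivityMatrix(subject_id, "functional", W, list(labels))


def anatomical_network(counts: np.ndarray, volumes: np.ndarray,
                       norm: str = "sum",
                       labels: list[str] | None = None,
                       subject_id: str = "") -> ConnectivityMatrix:
    """Volume-normalized fiber-density network.

    ``weight_ij = count_ij / (vol_i + vol_j)`` under the default
    ``sum`` convention (``product``: vol_i * vol_j; ``mean``: their
    average).
    """
    C = np.asarray(counts, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("counts must be a square matrix")
    if v.shape != (C.shape[0],):
        raise ValueError("volumes must have one entry per region")
    if (v <= 0).any():
        raise ValueError("volumes must be strictly positive")
    if (C < 0).any():
        raise ValueError("fiber counts must be nonnegative")
    if not np.array_equal(C, C.T):
        raise ValueError("fiber-count matrix must be symmetric")
    if norm not in ANAT_NORMS:
        raise ValueError(f"anat_norm must be one of {ANAT_NORMS}, "
                         f"got {norm!r}")
    if norm == "sum":
        denom = v[:, None] + v[None, :]
    elif norm == "product":
        denom = v[:, None] * v[None, :]
    else:
        denom = 0.5 * (v[:, None] + v[None, :])
    W = C / denom
    np.fill_diagonal(W, 0.0)
    if labels is None:
        labels = [str(i) for i in range(C.shape[0])]
    return ConnectivityMatrix(subject_id, "anatomical", W, list(labels))


def roi_indices(regions: pd.DataFrame,
                roi_labels: list[str] | None = None) -> list[int]:
    """Ordered node indices of the reporting ROIs within the atlas.

    Metrics are computed on the full network; this only selects which
    nodes get reported.  A missing label raises, naming the offender.
    """
    all_labels = list(regions["label"])
    if roi_labels is None:
        roi_labels = [lab for lab, flag in
                      zip(all_labels, regions["is_roi"]) if flag]
    pos = {lab: i for i, lab in enumerate(all_labels)}
    out = []
    for lab in roi_labels:
        if lab not in pos:
            raise KeyError(f"ROI label {lab!r} not present in parcellation")
        out.append(pos[lab])
    return out


def restrict_to_rois(matrices, regions: pd.DataFrame,
                     labels: list[str] | None = None):
    """Pair the full matrices with the ROI node index list."""
    return matrices, roi_indices(regions, labels)


class FunctionalConnectome(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`functional_network`.

    ``transform`` maps a list of (t, n_regions) arrays to a list of
    :class:`ConnectivityMatrix`.
    """

    def __init__(self, z_threshold: float = 0.3,
                 labels: list[str] | None = None):
        self.z_threshold = z_threshold
        self.labels = labels

    def fit(self, X, y=None):
        first = np.asarray(X[0])
        self.n_regions_ = first.shape[1]
        return self

    def transform(self, X, subject_ids=None):
        if subject_ids is None:
            subject_ids = [f"sub-{i + 1:03d}" for i in range(len(X))]
        return [functional_network(x, self.z_threshold, self.labels, sid)
                for x, sid in zip(X, subject_ids)]


class AnatomicalConnectome(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`anatomical_network`.

    Volumes are atlas metadata (subject-invariant), hence a parameter.
    """

    def __init__(self, volumes=None, norm: str = "sum",
                 labels: list[str] | None = None):
        self.volumes = volumes
        self.norm = norm
        self.labels = labels

    def fit(self, X, y=None):
        self.n_regions_ = np.asarray(X[0]).shape[0]
        return self

    def transform(self, X, subject_ids=None):
        if self.volumes is None:
            raise ValueError("volumes must be set before transform")
        if subject_ids is None:
            subject_ids = [f"sub-{i + 1:03d}" for i in range(len(X))]
        return [anatomical_network(x, self.volumes, self.norm,
                                   self.labels, sid)
                for x, sid in zip(X, subject_ids)]
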