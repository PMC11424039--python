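"""Bundle aggregation into weighted structural connectomes.

Kept streamlines are grouped into bundles by their endpoint-ROI pair and
each connectome entry aggregates the bundle's streamline weights:

    a_ij = sum_k x_k * l_k / (sum_k l_k / N_ij)

i.e. the length-weighted total intra-axonal signal fraction of the
bundle divided by its mean streamline length — the total IASF of the
connection. The conventional number-of-streamlines (NOS) weighting,
a_ij = N_ij, is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deconvolution import StreamlineWeights
from .parcellation import NetworkAssignment, Parcellation
from .phantom import Tractogram

__all__ = [
    "Bundle",
    "Connectome",
    "assign_endpoints",
    "edge_weight",
    "group_bundles",
    "build_connectome",
    "subnetwork_extract",
    "connection_density",
]


@dataclass
class Bundle:
    """All kept streamlines joining one unordered ROI pair."""

    roi_pair: tuple[int, int]
    member_ids: list[int]
    lengths: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.n_streamlines < 1:
            raise ValueError("a bundle needs at least one streamline")
        if np.any(self.lengths <= 0) or np.any(self.weights < 0):
            raise ValueError("lengths must be positive and weights non-negative")

    @property
    def n_streamlines(self) -> int:
        return len(self.member_ids)


@dataclass
class Connectome:
    """Symmetric non-negative weighted matrix over ROIs.

    ``labels`` gives the ROI label of each row/column; ``groups`` maps
    labels to canonical-network names when an assignment is attached.
    """

    matrix: np.ndarray
    labels: np.ndarray
    weighting: str = "IASF"
    roi_names: dict[int, str] = field(default_factory=dict)
    groups: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("connectome matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("edge weights must be non-negative")
        if np.any(np.diag(m) != 0):
            raise ValueError("connectome diagonal must be zero")
        self.matrix = m
        self.labels = np.asarray(self.labels)
        if self.labels.size != m.shape[0]:
            raise ValueError("labels must match matrix size")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


def assign_endpoints(
    tractogram: Tractogram, parcellation: Parcellation, radius_mm: float = 2.0
) -> Tractogram:
    """Attach endpoint ROI labels by containing voxel, else nearest label.

    An endpoint in a background voxel takes the label of the nearest
    labelled voxel centre within ``radius_mm``; an endpoint farther than
    that stays unassigned and the streamline is dropped from bundles
    (its ``endpoint_rois`` entry is None).
    """
    labels = parcellation.labels
    vox = parcellation.voxel_size
    labelled = np.argwhere(labels > 0)
    centers = (labelled + 0.5) * vox
    shape = np.array(labels.shape)

    def label_of(point: np.ndarray) -> int | None:
        idx = np.floor(point / vox).astype(int)
        if np.all(idx >= 0) and np.all(idx < shape):
            lab = int(labels[tuple(idx)])
            if lab > 0:
                return lab
        if labelled.size == 0:
            return None
        d = np.linalg.norm(centers - point, axis=1)
        j = int(np.argmin(d))
        if d[j] <= radius_mm:
            return int(labels[tuple(labelled[j])])
        return None

    pairs: list[tuple[int, int] | None] = []
    for sl in tractogram.streamlines:
        a = label_of(sl.points[0])
        b = label_of(sl.points[-1])
        pairs.append((a, b) if a is not None and b is not None else None)
    return Tractogram(tractogram.streamlines, pairs)


def edge_weight(bundle: Bundle) -> float:
    """Total IASF of a bundle: (sum x_k l_k) / (mean streamline length)."""
    total = float(np.sum(bundle.weights * bundle.lengths))
    mean_len = float(np.sum(bundle.lengths)) / bundle.n_streamlines
    return total / mean_len


def group_bundles(
    tractogram: Tractogram, weights: StreamlineWeights
) -> dict[tuple[int, int], Bundle]:
    """Group kept streamlines into inter-ROI bundles.

    Streamlines with unassigned endpoints, filtered-out streamlines and
    intra-ROI (i == j) streamlines contribute to no bundle.
    """
    if len(tractogram) != weights.x.size:
        raise ValueError("weights do not align with the tractogram")
    members: dict[tuple[int, int], list[int]] = {}
    for sid, pair in enumerate(tractogram.endpoint_rois):
        if pair is None or not weights.kept_mask[sid]:
            continue
        i, j = pair
        if i == j:
            continue
        members.setdefault((min(i, j), max(i, j)), []).append(sid)
    lengths = tractogram.lengths
    return {
        pair: Bundle(
            roi_pair=pair,
            member_ids=ids,
            lengths=lengths[ids],
            weights=weights.x[ids],
        )
        for pair, ids in members.items()
    }


def build_connectome(
    tractogram: Tractogram,
    weights: StreamlineWeights,
    parcellation: Parcellation,
    weighting: str = "IASF",
    assignment: NetworkAssignment | None = None,
) -> Connectome:
    """Bundle-aggregated connectome over the parcellation's ROIs.

    ``weighting='IASF'`` applies :func:`edge_weight` per bundle;
    ``weighting='NOS'`` uses the streamline count. ROIs with no kept
    bundle remain isolated nodes. Node order is (group, label) when an
    assignment is given, else label order.
    """
    if weighting not in ("IASF", "NOS"):
        raise ValueError(f"unknown weighting {weighting!r}")
    roi_labels = [int(r) for r in parcellation.roi_labels]
    groups = dict(assignment.mapping) if assignment is not None else {}
    if assignment is not None:
        roi_labels = [r for r in roi_labels if r in groups]
        roi_labels.sort(key=lambda r: (groups[r], r))
    index = {r: i for i, r in enumerate(roi_labels)}
    n = len(roi_labels)
    m = np.zeros((n, n))
    for pair, bundle in group_bundles(tractogram, weights).items():
        i, j = pair
        if i not in index or j not in index:
            continue
        w = edge_weight(bundle) if weighting == "IASF" else float(bundle.n_streamlines)
        m[index[i], index[j]] = w
        m[index[j], index[i]] = w
    return Connectome(
        matrix=m,
        labels=np.array(roi_labels),
        weighting=weighting,
        roi_names=dict(parcellation.roi_names),
        groups=groups,
    )


def subnetwork_extract(
    connectome: Connectome, assignment: NetworkAssignment, group: str
) -> Connectome:
    """Subgraph over one canonical network's nodes; between-group edges drop."""
    rois = assignment.rois_in(group)  # raises on unknown group
    mask = np.isin(connectome.labels, rois)
    if not mask.any():
        raise ValueError(f"no connectome nodes belong to group {group!r}")
    sub = connectome.matrix[np.ix_(mask, mask)]
    return Connectome(
        matrix=sub,
        labels=connectome.labels[mask],
        weighting=connectome.weighting,
        roi_names=connectome.roi_names,
        groups={int(r): group for r in connectome.labels[mask]},
    )


def connection_density(connectome: Connectome) -> float:
    """Fraction of possible (undirected) edges carrying nonzero weight."""
    n = connectome.n_rois
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    off = connectome.matrix[~np.eye(n, dtype=bool)]
    return float(np.count_nonzero(off)) / (n * (n - 1))
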