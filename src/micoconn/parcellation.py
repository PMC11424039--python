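"""Parcellations, canonical-network assignment and the atlas-merge rule.

A :class:`Parcellation` is an integer label volume (0 = background) with
optional ROI names and a homologous-ROI map (left/right counterparts).
:func:`merge_atlas` implements the data-driven rule that groups fine
cortical parcels into canonical networks: per subject each ROI goes to
the network with the largest voxel overlap, and an ROI is retained only
if that modal assignment is consistent across a minimum fraction of
subjects and agrees with its homologue.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Parcellation", "NetworkAssignment", "merge_atlas"]


@dataclass
class Parcellation:
    """Integer ROI label volume with metadata.

    Parameters
    ----------
    labels : 3-D int array
        ROI label per voxel; 0 is background, labels are positive.
    voxel_size : float
        Isotropic voxel edge in mm.
    roi_names : dict
        Optional label -> human-readable name.
    homolog_map : dict
        Optional label -> contralateral label; symmetric where defined.
    """

    labels: np.ndarray
    voxel_size: float = 2.0
    roi_names: dict[int, str] = field(default_factory=dict)
    homolog_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        for a, b in self.homolog_map.items():
            if self.homolog_map.get(b, a) != a:
                raise ValueError("homolog_map must be symmetric")

    @property
    def roi_labels(self) -> np.ndarray:
        """Sorted positive labels present in the volume."""
        labs = np.unique(self.labels)
        return labs[labs > 0]


@dataclass
class NetworkAssignment:
    """ROI -> canonical-network mapping with the per-ROI agreement trail."""

    mapping: dict[int, str]
    discarded: list[int] = field(default_factory=list)
    agreement: dict[int, float] = field(default_factory=dict)

    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def rois_in(self, group: str) -> list[int]:
        if group not in set(self.mapping.values()):
            raise ValueError(f"unknown group {group!r}")
        return sorted(r for r, g in self.mapping.items() if g == group)


def _modal_assignment(
    roi_mask: np.ndarray, network_masks: dict[str, np.ndarray]
) -> str | None:
    """Network with the maximum voxel-overlap count, None if all zero."""
    best, best_n = None, 0
    for name in sorted(network_masks):
        n = int(np.count_nonzero(roi_mask & network_masks[name]))
        if n > best_n:
            best, best_n = name, n
    return best


def merge_atlas(
    parcel_masks: list[dict[int, np.ndarray]],
    network_masks: list[dict[str, np.ndarray]],
    homolog_map: dict[int, int],
    min_agreement: float = 0.8,
) -> NetworkAssignment:
    """Assign fine ROIs to canonical networks by voxel-overlap consensus.

    Per subject, each ROI is assigned to the network whose mask shares the
    maximum number of voxels with the ROI mask. An ROI is retained iff

    * its across-subject modal network holds in at least ``min_agreement``
      of subjects (a subject where the ROI overlaps no network counts as
      disagreeing), and
    * its homologous ROI has the same modal network.

    Parameters
    ----------
    parcel_masks : list of dict
        One dict per subject: ROI label -> boolean voxel mask.
    network_masks : list of dict
        One dict per subject: network name -> boolean voxel mask, on the
        same grid as that subject's parcel masks.
    homolog_map : dict
        ROI label -> contralateral ROI label (symmetric).
    min_agreement : float
        Fraction of subjects that must share the modal assignment.

    Returns
    -------
    NetworkAssignment
        Retained mapping, the explicit discard list, and per-ROI modal
        agreement fractions.
    """
    if len(parcel_masks) != len(network_masks):
        raise ValueError("need one network-mask dict per subject")
    if not parcel_masks:
        raise ValueError("at least one subject required")
    n_subj = len(parcel_masks)
    rois = sorted({r for masks in parcel_masks for r in masks})

    votes: dict[int, Counter] = {r: Counter() for r in rois}
    seen: dict[int, int] = {r: 0 for r in rois}
    for pmasks, nmasks in zip(parcel_masks, network_masks):
        for r in rois:
            if r not in pmasks:
                continue
            seen[r] += 1
            assigned = _modal_assignment(pmasks[r], nmasks)
            if assigned is not None:
                votes[r][assigned] += 1

    modal: dict[int, str | None] = {}
    agreement: dict[int, float] = {}
    for r in rois:
        if votes[r]:
            # deterministic tie-break: highest count, then network name
            name, count = sorted(votes[r].items(), key=lambda kv: (-kv[1], kv[0]))[0]
            modal[r] = name
            agreement[r] = count / n_subj
        else:
            modal[r] = None
            agreement[r] = 0.0

    mapping: dict[int, str] = {}
    discarded: list[int] = []
    for r in rois:
        net = modal[r]
        if net is None or agreement[r] < min_agreement:
            discarded.append(r)
            continue
        mate = homolog_map.get(r)
        if mate is not None and modal.get(mate) != net:
            discarded.append(r)
            continue
        mapping[r] = net
    return NetworkAssignment(mapping=mapping, discarded=discarded, agreement=agreement)
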