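"""Voxel-overlap pocket similarity and reference-based grouping.

Similarity between two pockets of one entry is the fraction of the reference
pocket's voxels that the other pocket also occupies,

    P_ij = n_ij / N_i,

with n_ij the overlap count and N_i the reference's cell count.  P is
asymmetric but reciprocal: ``P_ij * N_i == P_ji * N_j == n_ij``.

Grouping uses the pockets of the first structural model as reference
conformations.  Every other pocket joins the reference it overlaps best,
provided that similarity exceeds the cutoff (default 0.25, strict); pockets
matching no reference are kept as leftover singleton groups.  Groups with
fewer than three members are flagged invalid and excluded from scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pocket_detect import GridPocket

__all__ = [
    "SimilarityMatrix",
    "PocketGroup",
    "pairwise_similarity",
    "build_matrix",
    "group_pockets",
]


@dataclass
class SimilarityMatrix:
    """q×q similarity of all pockets of an entry, in model/index label order."""

    labels: list[str]
    P: np.ndarray  # q×q, rows are reference pockets
    N: np.ndarray  # per-pocket cell counts
    pockets: list[GridPocket] = field(repr=False, default_factory=list)

    @property
    def q(self) -> int:
        return len(self.labels)

    def overlap_counts(self) -> np.ndarray:
        """n_ij, recovered as P_ij * N_i (integral up to float rounding)."""
        return self.P * self.N[:, None]


@dataclass
class PocketGroup:
    """Pockets clustered around one first-model reference (or a leftover)."""

    group_label: str
    reference: str  # pocket label of the reference conformation
    members: list[GridPocket]
    valid: bool = True

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def member_labels(self) -> list[str]:
        return [p.label for p in self.members]


def pairwise_similarity(pocket_i: GridPocket, pocket_j: GridPocket) -> float:
    """P_ij = |cells_i ∩ cells_j| / |cells_i| with pocket i as reference."""
    if (pocket_i.origin != pocket_j.origin
            or pocket_i.spacing != pocket_j.spacing):
        raise ValueError(
            "pockets live on different lattices; similarity is undefined")
    return len(pocket_i.cells & pocket_j.cells) / len(pocket_i.cells)


def build_matrix(pockets: list[GridPocket]) -> SimilarityMatrix:
    """All q² pairwise similarities, ordered as given (model, then index)."""
    if not pockets:
        raise ValueError("no pockets to compare")
    q = len(pockets)
    P = np.empty((q, q))
    for i, pi in enumerate(pockets):
        for j, pj in enumerate(pockets):
            P[i, j] = 1.0 if i == j else pairwise_similarity(pi, pj)
    return SimilarityMatrix(
        labels=[p.label for p in pockets],
        P=P,
        N=np.array([p.n_cells for p in pockets]),
        pockets=list(pockets),
    )


def group_pockets(
    matrix: SimilarityMatrix,
    cutoff: float = 0.25,
    entry_id: str = "ENTRY",
    min_members: int = 3,
) -> list[PocketGroup]:
    """Cluster pockets around the first structural model's pockets.

    A non-reference pocket j joins reference i when ``P[i, j] > cutoff``
    (strict); with several qualifying references the largest ``P[i, j]``
    wins (ties: lowest reference index).  Unmatched pockets become leftover
    singleton groups.  ``valid`` marks groups with ≥ ``min_members`` members.
    """
    pockets = matrix.pockets
    ref_idx = [k for k, p in enumerate(pockets) if p.model_index == 1]
    if not ref_idx:
        warnings.warn(
            f"{entry_id}: first structural model has no pockets; "
            "all pockets become leftover groups",
            stacklevel=2,
        )

    assigned: dict[int, int] = {}  # pocket index -> reference index
    for r in ref_idx:
        assigned[r] = r
    for j, pocket in enumerate(pockets):
        if j in assigned:
            continue
        best_r, best_p = None, cutoff
        for r in ref_idx:
            pij = matrix.P[r, j]
            if pij > best_p:  # strict cutoff; ties keep lowest ref index
                best_r, best_p = r, pij
        if best_r is not None:
            assigned[j] = best_r

    groups: list[PocketGroup] = []
    for gnum, r in enumerate(ref_idx, start=1):
        members = [pockets[j] for j in sorted(assigned) if assigned[j] == r]
        groups.append(
            PocketGroup(
                group_label=f"{entry_id}-G{gnum}",
                reference=pockets[r].label,
                members=members,
                valid=len(members) >= min_members,
            )
        )
    gnum = len(ref_idx)
    for j, pocket in enumerate(pockets):
        if j not in assigned:
            gnum += 1
            groups.append(
                PocketGroup(
                    group_label=f"{entry_id}-G{gnum}",
                    reference=pocket.label,
                    members=[pocket],
                    valid=1 >= min_members,
                )
            )
    return groups
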