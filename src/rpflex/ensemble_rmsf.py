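"""Nucleotide-averaged RMSF over an NMR ensemble and its pocket groups.

The RMSF of a nucleotide is the root-mean-square displacement of its
representative point across models, relative to a reference model:

    RMSF_j = sqrt( (1/m) * Σ_models |X_model − X_ref|² )

For a pocket group the calculation runs over the group's *overlapping
nucleotides* — residues lining strictly more than half of the group's
pockets — with the model of the group's first pocket as reference, and the
headline number is the mean over those ℓ nucleotides.  For a whole structure
it runs over every nucleotide of the RNA chain.

The representative point is the unweighted heavy-atom centroid of the
nucleotide by default (``representative='com'``); the C1' atom is available
as a single-atom alternative.  No superposition is applied: NMR depositions
are already aligned and coordinates are used as deposited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pocket_detect import GridPocket
from .pocket_similarity import PocketGroup
from .structure_io import Ensemble, StructureModel

__all__ = [
    "RmsfResult",
    "pocket_lining_nucleotides",
    "overlapping_nucleotides",
    "group_rmsf",
    "structure_rmsf",
]

ResidueID = tuple[str, int, str]


@dataclass
class RmsfResult:
    overlapping_nucleotides: list[ResidueID]
    per_nucleotide_rmsf: dict[ResidueID, float]
    mean_rmsf: float
    reference_model: int  # 1-based


def pocket_lining_nucleotides(
    pocket: GridPocket,
    model: StructureModel,
    contact_cutoff: float = 4.0,
    rna_chain: str | None = None,
) -> set[ResidueID]:
    """Nucleotides with ≥ 1 heavy atom within ``contact_cutoff`` Å of a cell."""
    tree = cKDTree(pocket.cell_centers())
    lining: set[ResidueID] = set()
    for res in model.rna_residues(rna_chain):
        coords = np.array([a.coords for a in res.heavy_atoms()])
        if coords.size and (tree.query(coords, k=1)[0] <= contact_cutoff).any():
            lining.add(res.id)
    return lining


def overlapping_nucleotides(
    group: PocketGroup,
    ensemble: Ensemble,
    contact_cutoff: float = 4.0,
) -> list[ResidueID]:
    """Residues lining strictly more than m/2 of the group's pockets.

    Each pocket's lining is evaluated in its own structural model.  The
    result is ordered by sequence position.
    """
    if not group.valid:
        raise ValueError(f"{group.group_label}: invalid group (m < 3)")
    counts: dict[ResidueID, int] = {}
    for pocket in group.members:
        model = ensemble.models[pocket.model_index - 1]
        for rid in pocket_lining_nucleotides(
                pocket, model, contact_cutoff, ensemble.rna_chain):
            counts[rid] = counts.get(rid, 0) + 1
    majority = group.m / 2
    out = sorted((rid for rid, c in counts.items() if c > majority),
                 key=lambda rid: (rid[0], rid[1], rid[2]))
    if not out:
        warnings.warn(
            f"{group.group_label}: no overlapping nucleotides; "
            "group unusable for RMSF",
            stacklevel=2,
        )
    return out


def _representative_points(
    model: StructureModel,
    residue_ids: list[ResidueID],
    representative: str,
) -> dict[ResidueID, np.ndarray]:
    points: dict[ResidueID, np.ndarray] = {}
    index = {r.id: r for r in model.residues}
    for rid in residue_ids:
        res = index.get(rid)
        if res is None:
            continue
        if representative == "com":
            coords = np.array([a.coords for a in res.heavy_atoms()])
            if coords.size:
                points[rid] = coords.mean(axis=0)
        elif representative == "C1prime":
            for atom in res.atoms:
                if atom.name in ("C1'", "C1*"):
                    points[rid] = atom.coords
                    break
        else:
            raise ValueError(f"unknown representative {representative!r}")
    return points


def _rmsf_over_models(
    ensemble: Ensemble,
    residue_ids: list[ResidueID],
    model_indices: list[int],
    reference_model: int,
    representative: str,
) -> RmsfResult:
    ref_points = _representative_points(
        ensemble.models[reference_model - 1], residue_ids, representative)
    skipped = [rid for rid in residue_ids if rid not in ref_points]
    for rid in skipped:
        warnings.warn(
            f"residue {rid}: missing representative atoms; skipped",
            stacklevel=3,
        )
    usable = [rid for rid in residue_ids if rid in ref_points]

    sq_disp = {rid: [] for rid in usable}
    for midx in model_indices:
        points = _representative_points(
            ensemble.models[midx - 1], usable, representative)
        for rid in usable:
            d = points[rid] - ref_points[rid]
            sq_disp[rid].append(float(d @ d))
    per_nt = {rid: float(np.sqrt(np.mean(sq))) for rid, sq in sq_disp.items()}
    mean = float(np.mean(list(per_nt.values()))) if per_nt else float("nan")
    return RmsfResult(
        overlapping_nucleotides=usable,
        per_nucleotide_rmsf=per_nt,
        mean_rmsf=mean,
        reference_model=reference_model,
    )


def group_rmsf(
    group: PocketGroup,
    ensemble: Ensemble,
    representative: str = "com",
    contact_cutoff: float = 4.0,
) -> RmsfResult:
    """Nucleotide-averaged RMSF of a pocket group's overlapping nucleotides.

    The reference positions come from the model that hosts the group's first
    pocket; the average runs over the models of all m member pockets.
    """
    overlap = overlapping_nucleotides(group, ensemble, contact_cutoff)
    if not overlap:
        raise ValueError(f"{group.group_label}: no overlapping nucleotides")
    first = min(group.members,
                key=lambda p: (p.model_index, p.pocket_index_in_model))
    return _rmsf_over_models(
        ensemble,
        overlap,
        [p.model_index for p in group.members],
        reference_model=first.model_index,
        representative=representative,
    )


def structure_rmsf(
    ensemble: Ensemble,
    reference_model_index: int = 1,
    representative: str = "com",
) -> RmsfResult:
    """RMSF over all nucleotides of the RNA chain and all models."""
    if ensemble.n_models < 2:
        raise ValueError("structure RMSF needs at least two models")
    residue_ids = [r.id for r in ensemble.models[0].rna_residues(
        ensemble.rna_chain)]
    return _rmsf_over_models(
        ensemble,
        residue_ids,
        list(range(1, ensemble.n_models + 1)),
        reference_model=reference_model_index,
        representative=representative,
    )
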