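"""Hydrogen-bond and van-der-Waals contact profiling by chemical group.

Hydrogen bonds follow HBPLUS-style distance criteria: donor–acceptor
distance < 3.35 Å and, when an explicit hydrogen bonded to the donor is
present (NMR entries usually deposit them), hydrogen–acceptor distance
< 2.7 Å.  Only distances are enforced — no angular terms.  Van-der-Waals
contacts are heavy-atom pairs in different residues closer than 3.9 Å that
are neither hydrogen-bonded nor covalently linked (the backbone O3'–P bond).

Contacts are categorized by the chemical groups of the two atoms.  Within
RNA the five pair categories are base–base (BB), ribose–base (RB),
phosphate–base (PB), phosphate–ribose (PR) and ribose–ribose (RR);
RNA–protein contacts carry the amino-acid category (charged / polar /
hydrophobic) and RNA–ligand contacts are split by the RNA side into
ligand–base and ligand–backbone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    ClassificationError,
    Residue,
    StructureModel,
    classify_chemical_group,
)

__all__ = [
    "ContactRecord",
    "ContactSummary",
    "find_hbonds",
    "find_vdw",
    "categorize",
    "summarize",
    "HBOND_DA_CUTOFF",
    "HBOND_HA_CUTOFF",
    "VDW_CUTOFF",
]

HBOND_DA_CUTOFF = 3.35  # Å, donor–acceptor
HBOND_HA_CUTOFF = 2.7  # Å, hydrogen–acceptor
VDW_CUTOFF = 3.9  # Å
COVALENT_H_CUTOFF = 1.3  # Å, hydrogen considered bonded to its donor
COVALENT_LINK_CUTOFF = 2.0  # Å, inter-residue covalent bond (O3'–P)

RNA_RNA_CATEGORY = {
    frozenset(["base"]): "BB",
    frozenset(["ribose", "base"]): "RB",
    frozenset(["phosphate", "base"]): "PB",
    frozenset(["phosphate", "ribose"]): "PR",
    frozenset(["ribose"]): "RR",
}

ResidueID = tuple[str, int, str]


def _load_tables() -> dict:
    with resources.files("rpflex.data").joinpath(
            "hbond_tables.json").open() as fh:
        return json.load(fh)


_TABLES = _load_tables()


@dataclass(frozen=True)
class ContactRecord:
    atom_names: tuple[str, str]
    residue_ids: tuple[ResidueID, ResidueID]
    residue_names: tuple[str, str]
    residue_kinds: tuple[str, str]
    groups: tuple[str, str]  # chemical group of each atom
    contact_type: str  # hbond | vdw
    distance: float

    @property
    def pair_key(self) -> frozenset:
        return frozenset([(self.residue_ids[0], self.atom_names[0]),
                          (self.residue_ids[1], self.atom_names[1])])


@dataclass
class ContactSummary:
    counts: dict[str, dict[str, int]]  # contact_type -> category -> count
    percentages: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.percentages:
            for ctype, cat_counts in self.counts.items():
                total = sum(cat_counts.values())
                self.percentages[ctype] = {
                    cat: (100.0 * n / total if total else 0.0)
                    for cat, n in cat_counts.items()
                }


# -- donor / acceptor lookups ------------------------------------------------

def _donor_acceptor_roles(res: Residue, atom: Atom) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) of one heavy atom."""
    if res.kind == "nucleotide":
        table = _TABLES["rna"]
        base = res.parent_base
        donors = set(table["common_donors"]) | set(
            table["donors"].get(base or "", []))
        acceptors = set(table["common_acceptors"]) | set(
            table["acceptors"].get(base or "", []))
        return atom.name in donors, atom.name in acceptors
    if res.kind == "amino_acid":
        table = _TABLES["protein"]
        donors = set(table["common_donors"]) | set(
            table["donors"].get(res.name, []))
        acceptors = set(table["common_acceptors"]) | set(
            table["acceptors"].get(res.name, []))
        return atom.name in donors, atom.name in acceptors
    table = _TABLES["ligand"]
    elem = atom.element.upper()
    return elem in table["donor_elements"], elem in table["acceptor_elements"]


def _chemical_group(res: Residue, atom: Atom) -> str:
    if res.kind in ("nucleotide", "amino_acid"):
        try:
            return classify_chemical_group(res, atom.name)
        except ClassificationError:
            return "other"
    if res.kind == "ligand":
        return "ligand"
    return "other"


def _scoped_residues(
    model: StructureModel,
    residue_scope: set[ResidueID] | None,
) -> list[Residue]:
    if residue_scope is None:
        return list(model.residues)
    return [r for r in model.residues if r.id in residue_scope]


def _covalent_pair(res_a: Residue, atom_a: Atom,
                   res_b: Residue, atom_b: Atom, dist: float) -> bool:
    """Inter-residue covalent linkage (backbone O3'–P or peptide C–N)."""
    if dist >= COVALENT_LINK_CUTOFF:
        return False
    names = {atom_a.name, atom_b.name}
    if names in ({"O3'", "P"}, {"O3*", "P"}) or names == {"C", "N"}:
        return True
    return False


# -- hydrogen bonds ----------------------------------------------------------

def find_hbonds(
    model: StructureModel,
    residue_scope: set[ResidueID] | None = None,
) -> list[ContactRecord]:
    """HBPLUS-style distance-criterion hydrogen bonds between residues.

    A donor–acceptor pair in different residues is a hydrogen bond when
    D–A < 3.35 Å and — if an explicit hydrogen covalently bonded to the
    donor exists — additionally H–A < 2.7 Å for at least one such hydrogen.
    """
    residues = _scoped_residues(model, residue_scope)
    donors: list[tuple[Residue, Atom]] = []
    acceptors: list[tuple[Residue, Atom]] = []
    hydrogens: dict[int, list[Atom]] = {}  # id(donor atom) -> bonded H's
    for res in residues:
        heavies = res.heavy_atoms()
        hs = [a for a in res.atoms if not a.is_heavy]
        for atom in heavies:
            is_d, is_a = _donor_acceptor_roles(res, atom)
            if is_d:
                donors.append((res, atom))
                bonded = [h for h in hs
                          if np.linalg.norm(h.coords - atom.coords)
                          <= COVALENT_H_CUTOFF]
                if bonded:
                    hydrogens[id(atom)] = bonded
            if is_a:
                acceptors.append((res, atom))
    if not donors or not acceptors:
        return []

    acc_tree = cKDTree(np.array([a.coords for _, a in acceptors]))
    records: list[ContactRecord] = []
    seen: set[frozenset] = set()
    for res_d, atom_d in donors:
        for j in acc_tree.query_ball_point(atom_d.coords, HBOND_DA_CUTOFF):
            res_a, atom_a = acceptors[j]
            if res_a.id == res_d.id:
                continue
            dist = float(np.linalg.norm(atom_d.coords - atom_a.coords))
            if dist >= HBOND_DA_CUTOFF:
                continue
            if _covalent_pair(res_d, atom_d, res_a, atom_a, dist):
                continue
            bonded_h = hydrogens.get(id(atom_d))
            if bonded_h is not None:
                ha = min(np.linalg.norm(h.coords - atom_a.coords)
                         for h in bonded_h)
                if ha >= HBOND_HA_CUTOFF:
                    continue
            key = frozenset([(res_d.id, atom_d.name), (res_a.id, atom_a.name)])
            if key in seen:
                continue
            seen.add(key)
            records.append(
                ContactRecord(
                    atom_names=(atom_d.name, atom_a.name),
                    residue_ids=(res_d.id, res_a.id),
                    residue_names=(res_d.name, res_a.name),
                    residue_kinds=(res_d.kind, res_a.kind),
                    groups=(_chemical_group(res_d, atom_d),
                            _chemical_group(res_a, atom_a)),
                    contact_type="hbond",
                    distance=dist,
                )
            )
    return records


# -- van der Waals contacts --------------------------------------------------

def find_vdw(
    model: StructureModel,
    residue_scope: set[ResidueID] | None = None,
    hbonds: list[ContactRecord] | None = None,
) -> list[ContactRecord]:
    """Heavy-atom pairs < 3.9 Å apart that are neither H-bonded nor covalent."""
    if hbonds is None:
        hbonds = find_hbonds(model, residue_scope)
    hbond_pairs = {rec.pair_key for rec in hbonds}

    residues = _scoped_residues(model, residue_scope)
    flat: list[tuple[Residue, Atom]] = [
        (res, a) for res in residues for a in res.heavy_atoms()]
    if len(flat) < 2:
        return []
    tree = cKDTree(np.array([a.coords for _, a in flat]))
    records: list[ContactRecord] = []
    for i, j in tree.query_pairs(VDW_CUTOFF):
        res_a, atom_a = flat[i]
        res_b, atom_b = flat[j]
        if res_a.id == res_b.id:
            continue
        dist = float(np.linalg.norm(atom_a.coords - atom_b.coords))
        if dist >= VDW_CUTOFF:
            continue
        key = frozenset([(res_a.id, atom_a.name), (res_b.id, atom_b.name)])
        if key in hbond_pairs:
            continue
        if _covalent_pair(res_a, atom_a, res_b, atom_b, dist):
            continue
        records.append(
            ContactRecord(
                atom_names=(atom_a.name, atom_b.name),
                residue_ids=(res_a.id, res_b.id),
                residue_names=(res_a.name, res_b.name),
                residue_kinds=(res_a.kind, res_b.kind),
                groups=(_chemical_group(res_a, atom_a),
                        _chemical_group(res_b, atom_b)),
                contact_type="vdw",
                distance=dist,
            )
        )
    return records


# -- categorization and summaries --------------------------------------------

def categorize(record: ContactRecord) -> str:
    """Pair category of one contact.

    RNA–RNA → one of BB/RB/PB/PR/RR; RNA–protein → the amino-acid category;
    RNA–ligand → 'ligand-base' or 'ligand-backbone' by the RNA-side group.
    """
    kinds = record.residue_kinds
    groups = record.groups
    if kinds == ("nucleotide", "nucleotide"):
        return RNA_RNA_CATEGORY.get(frozenset(groups), "other")
    if "amino_acid" in kinds:
        aa_group = groups[kinds.index("amino_acid")]
        return aa_group if aa_group in (
            "charged", "polar", "hydrophobic") else "other"
    if "ligand" in kinds and "nucleotide" in kinds:
        rna_group = groups[kinds.index("nucleotide")]
        if rna_group == "base":
            return "ligand-base"
        if rna_group in ("ribose", "phosphate"):
            return "ligand-backbone"
    return "other"


def summarize(
    records: list[ContactRecord],
    scope: set[ResidueID] | None = None,
) -> ContactSummary:
    """Counts and percentages per category, separately for hbond and vdw.

    ``scope`` restricts to contacts whose RNA residues all belong to the
    given (pocket-lining) residue set.  Percentages are normalized within
    each contact type over the categorized (non-'other') records.
    """
    counts: dict[str, dict[str, int]] = {"hbond": {}, "vdw": {}}
    kept = 0
    for rec in records:
        if scope is not None:
            rna_ids = [rid for rid, kind in
                       zip(rec.residue_ids, rec.residue_kinds)
                       if kind == "nucleotide"]
            if not all(rid in scope for rid in rna_ids):
                continue
        cat = categorize(rec)
        if cat == "other":
            continue
        counts[rec.contact_type][cat] = counts[rec.contact_type].get(cat, 0) + 1
        kept += 1
    if kept == 0:
        warnings.warn("no categorizable contacts; all-zero summary",
                      stacklevel=2)
    return ContactSummary(counts=counts)
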