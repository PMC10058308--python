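"""Structure I/O: multi-model PDB ensembles with residue typing.

An NMR deposition contains several structural models of the same molecule
(MODEL/ENDMDL blocks).  This module parses such files into an :class:`Ensemble`
whose models share one residue topology, classifies residues (nucleotide,
amino acid, ligand) and partitions nucleotide heavy atoms into the three
chemical groups used throughout the pipeline: phosphate, ribose and base.

Parsing is delegated to Biopython's ``Bio.PDB``; a small fixed-format emitter
writes models and pocket dummy atoms back out so that synthetic fixtures
exercise the same I/O path as deposited entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Ensemble",
    "TopologyError",
    "ClassificationError",
    "read_multimodel_pdb",
    "classify_chemical_group",
    "heavy_atoms",
    "write_model_pdb",
]


class TopologyError(ValueError):
    """Models of one entry do not share the same residue topology."""


class ClassificationError(KeyError):
    """A residue or atom name has no chemical-group assignment."""


# -- residue vocabularies ----------------------------------------------------

STANDARD_NUCLEOTIDES = {"A", "U", "G", "C", "I"}

#: modified nucleotides mapped to their parent base; extend as needed
MODIFIED_NUCLEOTIDE_PARENT = {
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "OMU": "U", "UR3": "U",
    "1MA": "A", "MA6": "A", "6MZ": "A", "A2M": "A",
    "5MC": "C", "OMC": "C", "CBV": "C",
    "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "1MG": "G", "YG": "G",
}

AMINO_ACID_CATEGORY = {
    # charged
    "ASP": "charged", "GLU": "charged", "LYS": "charged", "ARG": "charged",
    "HIS": "charged",
    # polar
    "CYS": "polar", "ASN": "polar", "GLN": "polar", "SER": "polar",
    "THR": "polar", "TYR": "polar",
    # hydrophobic
    "ALA": "hydrophobic", "PHE": "hydrophobic", "GLY": "hydrophobic",
    "ILE": "hydrophobic", "LEU": "hydrophobic", "TRP": "hydrophobic",
    "MET": "hydrophobic", "PRO": "hydrophobic", "VAL": "hydrophobic",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: phosphate = PO4 core only; O5'/O3' belong to ribose so the partition is
#: unambiguous at 5'/3' termini (bridging oxygens are sugar-derived).
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}
RIBOSE_ATOMS = {
    "C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O3'", "O4'", "O5'",
    "C1*", "C2*", "C3*", "C4*", "C5*", "O2*", "O3*", "O4*", "O5*",
}


# -- data model --------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom: PDB name, element symbol and Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """One residue with its atoms and a coarse kind classification."""

    chain: str
    number: int
    icode: str
    name: str
    kind: str  # nucleotide | amino_acid | ligand | other
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.name}{self.number}{self.icode}".strip()

    @property
    def parent_base(self) -> str | None:
        """One-letter parent base for a (possibly modified) nucleotide."""
        if self.kind != "nucleotide":
            return None
        if self.name in STANDARD_NUCLEOTIDES:
            return self.name
        return MODIFIED_NUCLEOTIDE_PARENT.get(self.name)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class StructureModel:
    """One conformer of the ensemble; residues in deposition order."""

    residues: list[Residue] = field(default_factory=list)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def residues_of_kind(self, kind: str) -> list[Residue]:
        return [r for r in self.residues if r.kind == kind]

    def rna_residues(self, chain: str | None = None) -> list[Residue]:
        return [
            r for r in self.residues
            if r.kind == "nucleotide" and (chain is None or r.chain == chain)
        ]


@dataclass
class Ensemble:
    """An ordered set of structural models sharing one residue topology."""

    entry_id: str
    models: list[StructureModel]
    rna_chain: str
    partner_kind: str  # none | ligand | protein

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble has no models")
        if self.n_models == 1:
            warnings.warn(
                f"{self.entry_id}: single-model entry; flexibility analysis "
                "requires several models",
                stacklevel=2,
            )

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def single_model(self) -> bool:
        return self.n_models == 1


# -- classification ----------------------------------------------------------

def _residue_kind(resname: str, is_hetero: bool) -> str:
    if resname in STANDARD_NUCLEOTIDES or resname in MODIFIED_NUCLEOTIDE_PARENT:
        return "nucleotide"
    if resname in AMINO_ACID_CATEGORY:
        return "amino_acid"
    if is_hetero:
        return "ligand"
    return "other"


def classify_chemical_group(residue: Residue, atom_name: str) -> str:
    """Chemical group of one atom.

    Nucleotides partition into ``phosphate`` ({P, OP1, OP2, OP3}), ``ribose``
    (C1'–C5', O2'–O5') and ``base`` (every remaining heavy atom); amino acids
    map by residue name alone onto ``charged`` (Asp, Glu, Lys, Arg, His),
    ``polar`` (Cys, Asn, Gln, Ser, Thr, Tyr) or ``hydrophobic`` (the rest).
    """
    if residue.kind == "nucleotide":
        if atom_name in PHOSPHATE_ATOMS:
            return "phosphate"
        if atom_name in RIBOSE_ATOMS:
            return "ribose"
        if atom_name.upper().startswith(("H", "D")) or atom_name in ("1H", "2H"):
            raise ClassificationError(
                f"hydrogen {atom_name} carries no chemical group")
        return "base"
    if residue.kind == "amino_acid":
        try:
            return AMINO_ACID_CATEGORY[residue.name]
        except KeyError:
            raise ClassificationError(
                f"unknown amino acid {residue.name}") from None
    raise ClassificationError(
        f"residue {residue.name} ({residue.kind}) has no chemical groups")


def heavy_atoms(
    model: StructureModel,
    residue_subset: Iterable[tuple[str, int, str]] | None = None,
) -> list[tuple[Residue, Atom]]:
    """All (residue, atom) pairs with element ≠ H, in residue order."""
    wanted = set(residue_subset) if residue_subset is not None else None
    out: list[tuple[Residue, Atom]] = []
    for res in model.residues:
        if wanted is not None and res.id not in wanted:
            continue
        out.extend((res, a) for a in res.atoms if a.is_heavy)
    return out


# -- reading -----------------------------------------------------------------

def _element_of(biopdb_atom) -> str:
    elem = (biopdb_atom.element or "").strip()
    if elem:
        return elem.capitalize()
    name = biopdb_atom.get_name().strip()
    # strip leading digits of names like "1H5'"
    stripped = name.lstrip("0123456789")
    return (stripped[:1] or "X").capitalize()


def read_multimodel_pdb(
    path: str | Path,
    rna_chain: str | None = None,
    entry_id: str | None = None,
) -> Ensemble:
    """Parse a multi-model PDB file into an :class:`Ensemble`.

    One :class:`StructureModel` is produced per MODEL block, in file order
    (a file without MODEL records yields a single model).  Waters are
    discarded; other HETATM residues are kept with ``kind='ligand'``.  For
    alternate locations Biopython's default conformer (highest occupancy)
    is used.  Residue topology is required to be identical across models.
    """
    path = Path(path)
    if entry_id is None:
        entry_id = path.stem[:4].upper() or "XXXX"
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(entry_id, str(path))

    models: list[StructureModel] = []
    for bio_model in structure:
        residues: list[Residue] = []
        for bio_chain in bio_model:
            for bio_res in bio_chain:
                hetflag, resseq, icode = bio_res.id
                resname = bio_res.get_resname().strip()
                if resname in WATER_NAMES or hetflag == "W":
                    continue
                kind = _residue_kind(resname, hetflag.strip() != "")
                res = Residue(
                    chain=bio_chain.id,
                    number=resseq,
                    icode=icode.strip(),
                    name=resname,
                    kind=kind,
                )
                for bio_atom in bio_res:
                    res.atoms.append(
                        Atom(
                            name=bio_atom.get_name().strip(),
                            element=_element_of(bio_atom),
                            coords=np.array(bio_atom.get_coord(), dtype=float),
                        )
                    )
                residues.append(res)
        models.append(StructureModel(residues=residues))

    if not models:
        raise ValueError(f"{path}: no models found")

    topo0 = [(r.id, r.name) for r in models[0].residues]
    for k, model in enumerate(models[1:], start=2):
        topo = [(r.id, r.name) for r in model.residues]
        if topo != topo0:
            raise TopologyError(
                f"{entry_id}: model {k} residue topology differs from model 1")

    if rna_chain is None:
        counts: dict[str, int] = {}
        for r in models[0].residues:
            if r.kind == "nucleotide":
                counts[r.chain] = counts.get(r.chain, 0) + 1
        if not counts:
            raise ValueError(f"{entry_id}: no RNA chain found")
        rna_chain = max(counts, key=lambda c: (counts[c], c))
    elif not any(
        r.kind == "nucleotide" and r.chain == rna_chain
        for r in models[0].residues
    ):
        raise ValueError(f"{entry_id}: chain {rna_chain} contains no nucleotides")

    has_protein = any(r.kind == "amino_acid" for r in models[0].residues)
    has_ligand = any(r.kind == "ligand" for r in models[0].residues)
    partner = "protein" if has_protein else ("ligand" if has_ligand else "none")

    return Ensemble(
        entry_id=entry_id,
        models=models,
        rna_chain=rna_chain,
        partner_kind=partner,
    )


# -- writing -----------------------------------------------------------------

def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resseq: int,
    icode: str, xyz: Sequence[float], element: str, hetatm: bool,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    # PDB v3 name justification: 4-char field, element-aligned
    if len(name) < 4 and len(element) == 1:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    return (
        f"{record}{serial:>5d} {name_f} {resname:<3s} {chain:1s}"
        f"{resseq:>4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element.upper():>2s}"
    )


def write_model_pdb(
    models: StructureModel | Sequence[StructureModel],
    path: str | Path,
) -> None:
    """Write one or several models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    lines: list[str] = []
    multi = len(models) > 1
    for midx, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {midx:>4d}")
        serial = 1
        for res in model.residues:
            for atom in res.atoms:
                lines.append(
                    _pdb_atom_line(
                        serial, atom.name, res.name, res.chain, res.number,
                        res.icode, atom.coords, atom.element,
                        hetatm=res.kind == "ligand",
                    )
                )
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
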