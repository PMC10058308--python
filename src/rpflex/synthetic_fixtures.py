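"""Deterministic synthetic inputs for every pipeline stage.

Four fixture families, all reproducible from (parameters, seed):

* digitized voxel solids (sphere, box) with the analytic volume attached,
  for voxel-metric convergence checks;
* pseudo-atom shells sealing a spherical cavity of known volume, for the
  two-probe detector;
* multi-model ensembles built by rigidly displacing each nucleotide of a
  template with zero-mean Gaussian noise of scale ``s`` Å — the dial that
  emulates how much an NMR ensemble's conformers disagree;
* toy graphs (path, cycle, complete, random) with hand-computable metrics.

The synthetic RNA template is a ring of ``n`` coarse nucleotides whose bases
point inward, enclosing an open axial channel: wide enough for the small
probe, too narrow for the large one, so pocket detection is guaranteed to
find a central pocket in every model.  The geometry is a deliberately crude
stand-in for a folded RNA — plausible atom names, spacing and size, but no
base pairing, stacking energetics or backbone torsion realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .contact_network import PocketNetwork
from .pocket_detect import GridPocket
from .structure_io import Atom, Ensemble, Residue, StructureModel

__all__ = [
    "VoxelShape",
    "make_voxel_shape",
    "make_cavity_shell",
    "make_rna_template",
    "make_perturbed_ensemble",
    "make_toy_graph",
]


@dataclass(frozen=True)
class VoxelShape:
    pocket: GridPocket
    analytic_volume: float  # Å³
    analytic_area: float  # Å² of the smooth solid (not the lattice estimate)


def make_voxel_shape(
    kind: str,
    size: float,
    spacing: float = 1.0,
) -> VoxelShape:
    """Digitize a solid on the lattice (cell centres inside the solid).

    ``kind='sphere'`` uses ``size`` as the radius; ``kind='box'`` as the edge
    length.  The analytic volume/area of the smooth solid ride along for
    convergence tests.
    """
    if size <= spacing:
        raise ValueError("size must exceed spacing")
    if kind == "sphere":
        r = size
        n = int(np.ceil(r / spacing)) + 1
        rng = np.arange(-n, n + 1)
        ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
        centers = (np.stack([ii, jj, kk], axis=-1) + 0.5) * spacing
        inside = (centers**2).sum(axis=-1) <= r**2
        cells = np.argwhere(inside) - n
        analytic_v = 4 / 3 * np.pi * r**3
        analytic_a = 4 * np.pi * r**2
    elif kind == "box":
        n = int(round(size / spacing))
        rng = np.arange(n)
        ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
        cells = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        analytic_v = size**3
        analytic_a = 6 * size**2
    else:
        raise ValueError(f"unknown voxel shape {kind!r}")
    pocket = GridPocket(
        cells=frozenset(map(tuple, cells.tolist())),
        model_index=1,
        pocket_index_in_model=1,
        origin=(0.0, 0.0, 0.0),
        spacing=spacing,
    )
    return VoxelShape(pocket=pocket, analytic_volume=analytic_v,
                      analytic_area=analytic_a)


def make_cavity_shell(
    inner_radius: float,
    shell_thickness: float,
    atom_spacing: float = 1.0,
    seed: int = 0,
    centers: list[tuple[float, float, float]] | None = None,
    jitter: float = 0.0,
) -> StructureModel:
    """Dense pseudo-atom shell(s) sealing spherical cavities of known volume.

    ``inner_radius`` is the radius of the *empty* cavity: atom centres
    (carbon, vdW 1.7 Å) sit on a cubic lattice of pitch ``atom_spacing``
    wherever ``inner_radius + r_vdw ≤ |x − c| ≤ inner_radius + r_vdw +
    shell_thickness`` for a cavity centre c, so the van der Waals surface of
    the innermost atoms bounds a free sphere of the stated radius.  With
    pitch ≤ ~1.5 Å the shell is impermeable to a 3 Å probe.  ``jitter``
    adds seeded Gaussian noise of that scale to every atom.
    """
    if shell_thickness < 2 * atom_spacing:
        raise ValueError("shell too thin to seal the cavity")
    if centers is None:
        centers = [(0.0, 0.0, 0.0)]
    centers_arr = np.asarray(centers, dtype=float)
    carbon_vdw = 1.70
    inner_radius = inner_radius + carbon_vdw
    outer = inner_radius + shell_thickness
    lo = centers_arr.min(axis=0) - outer
    hi = centers_arr.max(axis=0) + outer
    axes = [np.arange(lo[d], hi[d] + atom_spacing / 2, atom_spacing)
            for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.min(
        np.linalg.norm(grid[:, None, :] - centers_arr[None, :, :], axis=-1),
        axis=1,
    )
    coords = grid[(dist >= inner_radius) & (dist <= outer)]
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)

    # chunk atoms into pseudo-residues so the model satisfies the data model
    residues: list[Residue] = []
    chunk = 50
    for rnum, start in enumerate(range(0, len(coords), chunk), start=1):
        res = Residue(chain="S", number=rnum, icode="", name="SHL",
                      kind="other")
        for k, xyz in enumerate(coords[start:start + chunk], start=1):
            res.atoms.append(Atom(name=f"C{k}", element="C", coords=xyz))
        residues.append(res)
    return StructureModel(residues=residues)


# -- synthetic RNA -----------------------------------------------------------

_BASE_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "U": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"],
}


def _nucleotide_local_atoms(base: str) -> list[tuple[str, np.ndarray]]:
    """Crude heavy-atom layout of one nucleotide in a local frame.

    Backbone near the origin, ribose ring around x ≈ 2–4, base ring atoms on
    a circle around x ≈ 6.  +x is the direction the base points.
    """
    atoms: list[tuple[str, np.ndarray]] = [
        ("P", np.array([0.0, 0.0, 0.0])),
        ("OP1", np.array([-0.8, 1.2, 0.3])),
        ("OP2", np.array([-0.8, -1.2, 0.3])),
        ("O5'", np.array([1.3, 0.0, 0.8])),
        ("C5'", np.array([2.3, 0.7, 1.1])),
    ]
    # ribose: pentagon in the xz-plane
    ribose = ["C4'", "O4'", "C1'", "C2'", "C3'"]
    for k, name in enumerate(ribose):
        ang = 2 * np.pi * k / 5
        atoms.append(
            (name, np.array([3.3 + 1.2 * np.cos(ang), 0.2,
                             0.6 + 1.2 * np.sin(ang)])))
    atoms.append(("O2'", np.array([4.1, 1.3, -0.6])))
    atoms.append(("O3'", np.array([2.6, -0.4, -1.4])))
    # base: ring atoms on a circle in the xy-plane
    names = _BASE_ATOMS[base]
    for k, name in enumerate(names):
        ang = 2 * np.pi * k / len(names)
        atoms.append(
            (name, np.array([6.2 + 1.5 * np.cos(ang),
                             1.5 * np.sin(ang), 0.0])))
    return atoms


def make_rna_template(
    n_residues: int = 20,
    sequence: str | None = None,
    rise: float = 0.0,
    chain: str = "A",
) -> StructureModel:
    """Ring-shaped synthetic RNA with an axial channel pocket.

    ``n_residues`` coarse nucleotides sit on a circle (neighbour spacing
    ≈ 4.5 Å along the backbone) with their bases pointing inward; the open
    centre is reachable by a 3 Å probe but not a 10 Å one.  ``rise`` lifts
    consecutive residues to turn the ring into a helix turn.
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues to close the ring")
    if sequence is None:
        sequence = "".join("GCAU"[i % 4] for i in range(n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length must match n_residues")
    radius = n_residues * 4.5 / (2 * np.pi)
    residues: list[Residue] = []
    for i, base in enumerate(sequence):
        theta = 2 * np.pi * i / n_residues
        # local +x must point toward the ring axis (inward)
        inward = -np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        up = np.array([0.0, 0.0, 1.0])
        frame = np.column_stack([inward, tangent, up])
        anchor = np.array([radius * np.cos(theta), radius * np.sin(theta),
                           rise * i])
        res = Residue(chain=chain, number=i + 1, icode="", name=base,
                      kind="nucleotide")
        for name, local in _nucleotide_local_atoms(base):
            res.atoms.append(
                Atom(name=name, element=name[0], coords=anchor + frame @ local))
        residues.append(res)
    return StructureModel(residues=residues)


def make_perturbed_ensemble(
    template: StructureModel,
    n_models: int = 10,
    s: float = 0.5,
    seed: int = 0,
    entry_id: str = "SYNT",
) -> Ensemble:
    """Ensemble of rigid per-residue Gaussian perturbations of a template.

    Model 1 is the template itself; each later model displaces every residue
    as a rigid unit by an independent zero-mean isotropic Gaussian vector of
    scale ``s`` Å per coordinate.  Per-residue (not per-atom) displacement
    keeps the nucleotide-level RMSF in closed form: for one perturbed model
    against the template the expected squared displacement is 3s².
    """
    if n_models < 3:
        raise ValueError("need n_models >= 3")
    if s < 0:
        raise ValueError("need s >= 0")
    rng = np.random.default_rng(seed)
    models = [template]
    for _ in range(n_models - 1):
        residues = []
        for res in template.residues:
            shift = rng.normal(scale=s, size=3) if s > 0 else np.zeros(3)
            new = Residue(chain=res.chain, number=res.number, icode=res.icode,
                          name=res.name, kind=res.kind)
            for atom in res.atoms:
                new.atoms.append(
                    Atom(name=atom.name, element=atom.element,
                         coords=atom.coords + shift))
            residues.append(new)
        models.append(StructureModel(residues=residues))

    chains = {r.chain for r in template.residues if r.kind == "nucleotide"}
    rna_chain = sorted(chains)[0] if chains else "A"
    has_protein = any(r.kind == "amino_acid" for r in template.residues)
    has_ligand = any(r.kind == "ligand" for r in template.residues)
    partner = "protein" if has_protein else ("ligand" if has_ligand else "none")
    return Ensemble(entry_id=entry_id, models=models, rna_chain=rna_chain,
                    partner_kind=partner)


def make_toy_graph(
    kind: str,
    n: int,
    seed: int = 0,
    p: float = 0.4,
) -> PocketNetwork:
    """Named toy topologies with known metrics (nodes are integers)."""
    if n < 1:
        raise ValueError("need n >= 1")
    if kind == "path":
        g = nx.path_graph(n)
    elif kind == "cycle":
        g = nx.cycle_graph(n)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "random":
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown toy graph kind {kind!r}")
    return PocketNetwork(graph=g, model_index=1)
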