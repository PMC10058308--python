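"""Pocket-lining nucleotides, overlapping nucleotides and ensemble RMSF."""

import numpy as np
import pytest
from scipy import stats

from rpflex.ensemble_rmsf import (
    group_rmsf,
    overlapping_nucleotides,
    pocket_lining_nucleotides,
    structure_rmsf,
)
from rpflex.pocket_detect import GridPocket, detect_pockets
from rpflex.pocket_similarity import PocketGroup
from rpflex.structure_io import Atom, Ensemble, Residue, StructureModel
from rpflex.synthetic_fixtures import make_perturbed_ensemble


def _nt(chain, num, xyz, name="G"):
    res = Residue(chain, num, "", name, "nucleotide")
    res.atoms.append(Atom("C1'", "C", xyz))
    return res


def _pocket(cells, model=1, index=1):
    return GridPocket(frozenset(cells), model, index, (0.0, 0.0, 0.0), 1.0)


def _two_residue_ensemble(far_offset):
    """Two nucleotides; the second sits ``far_offset`` from the pocket."""
    models = []
    for _ in range(4):
        models.append(StructureModel([
            _nt("A", 1, [1.0, 0.5, 0.5]),
            _nt("A", 2, np.array([1.0, 0.5, 0.5]) + far_offset),
        ]))
    return Ensemble("TEST", models, "A", "none")


def test_pocket_lining_examples():
    model = StructureModel([_nt("A", 5, [1.5, 0.5, 0.5])])
    pocket = _pocket({(0, 0, 0)})  # cell centre at (0.5, 0.5, 0.5): 1 Å away
    assert pocket_lining_nucleotides(pocket, model) == {("A", 5, "")}
    far = StructureModel([_nt("A", 5, [20.0, 0.0, 0.0])])
    assert pocket_lining_nucleotides(pocket, far) == set()


def test_lining_cutoff_sweep_monotone(ring_template):
    (pocket,) = detect_pockets(ring_template, min_volume=100)
    previous = set()
    for cutoff in (3.0, 3.5, 4.0, 4.5, 5.0):
        lining = pocket_lining_nucleotides(pocket, ring_template, cutoff)
        assert previous <= lining
        previous = lining


def test_overlapping_majority_is_strict():
    """A residue lining exactly m/2 of the pockets (m = 4) is excluded."""
    ens = _two_residue_ensemble(far_offset=np.array([30.0, 0.0, 0.0]))
    near = {(0, 0, 0)}
    far = {(30, 0, 0)}
    # residue 2 lines pockets of models 3 and 4 only (2 of 4 = exactly half)
    members = [
        _pocket(near, model=1),
        _pocket(near, model=2),
        _pocket(near | far, model=3),
        _pocket(near | far, model=4),
    ]
    group = PocketGroup("TEST-G1", "m1-1", members, valid=True)
    assert overlapping_nucleotides(group, ens) == [("A", 1, "")]

    # lining 3 of 4 pockets clears the strict majority
    members[1] = _pocket(near | far, model=2)
    group3 = PocketGroup("TEST-G1", "m1-1", members, valid=True)
    assert overlapping_nucleotides(group3, ens) == [("A", 1, ""), ("A", 2, "")]


def test_rmsf_zero_on_duplicate_models(ring_template):
    models = [ring_template] * 5
    ens = Ensemble("DUP", models, "A", "none")
    res = structure_rmsf(ens)
    assert all(v == 0 for v in res.per_nucleotide_rmsf.values())
    assert res.mean_rmsf == 0


def test_rmsf_closed_form_two_models():
    """One nucleotide displaced by d in the second of two models → d/√2."""
    d = 1.8
    m1 = StructureModel([_nt("A", 1, [0.0, 0.0, 0.0])])
    m2 = StructureModel([_nt("A", 1, [d, 0.0, 0.0])])
    ens = Ensemble("TWO", [m1, m2], "A", "none")
    res = structure_rmsf(ens)
    assert res.per_nucleotide_rmsf[("A", 1, "")] == pytest.approx(d / np.sqrt(2))


def test_rmsf_rigid_translation_invariant(small_ensemble):
    base = structure_rmsf(small_ensemble)
    shift = np.array([7.0, -3.0, 2.0])
    shifted_models = []
    for model in small_ensemble.models:
        residues = []
        for res in model.residues:
            new = Residue(res.chain, res.number, res.icode, res.name, res.kind)
            new.atoms = [Atom(a.name, a.element, a.coords + shift)
                         for a in res.atoms]
            residues.append(new)
        shifted_models.append(StructureModel(residues))
    ens = Ensemble(small_ensemble.entry_id, shifted_models,
                   small_ensemble.rna_chain, small_ensemble.partner_kind)
    res = structure_rmsf(ens)
    for rid, v in base.per_nucleotide_rmsf.items():
        assert res.per_nucleotide_rmsf[rid] == pytest.approx(v)


def test_rmsf_scales_with_displacement():
    """Doubling every displacement from the reference doubles the RMSF."""
    rng = np.random.default_rng(1)
    base_xyz = np.zeros(3)
    disp = rng.normal(size=(4, 3))
    for scale in (1.0, 2.0):
        models = [StructureModel([_nt("A", 1, base_xyz)])]
        models += [StructureModel([_nt("A", 1, base_xyz + scale * d)])
                   for d in disp]
        ens = Ensemble("SCL", models, "A", "none")
        if scale == 1.0:
            ref = structure_rmsf(ens).mean_rmsf
        else:
            assert structure_rmsf(ens).mean_rmsf == pytest.approx(2 * ref)


def test_rmsf_matches_chi_expectation(ring_template):
    """Gaussian per-nucleotide displacement of scale s: each RMSF equals
    (s/√m)·χ with 3(m−1) degrees of freedom; the sample mean over ℓ
    nucleotides must fall within 3 standard errors of the exact mean."""
    s, m = 1.0, 10
    ens = make_perturbed_ensemble(ring_template, n_models=m, s=s, seed=123)
    res = structure_rmsf(ens)
    values = np.array(list(res.per_nucleotide_rmsf.values()))
    chi = stats.chi(3 * (m - 1), scale=s / np.sqrt(m))
    se = chi.std() / np.sqrt(len(values))
    assert abs(values.mean() - chi.mean()) < 3 * se


def test_group_rmsf_monotone_in_s(ring_template):
    """Larger ensemble perturbation gives larger group RMSF (coupled seeds)."""
    from rpflex.pipeline import run_entry

    means = []
    for s in (0.1, 0.3, 0.6, 0.9, 1.2):
        ens = make_perturbed_ensemble(ring_template, n_models=6, s=s, seed=77)
        rep = run_entry(ens)
        group = next(g for g in rep.groups if g.get("valid"))
        means.append(group["rmsf"]["mean_rmsf"])
    assert means == sorted(means)
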