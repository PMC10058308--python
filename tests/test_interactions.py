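"""Hydrogen-bond / vdW contact detection and chemical-group categories."""

import numpy as np
import pytest

from rpflex.interactions import (
    ContactRecord,
    categorize,
    find_hbonds,
    find_vdw,
    summarize,
)
from rpflex.structure_io import Atom, Residue, StructureModel


def _res(chain, num, name, kind, atoms):
    res = Residue(chain, num, "", name, kind)
    for aname, elem, xyz in atoms:
        res.atoms.append(Atom(aname, elem, xyz))
    return res


def _wc_gc_pair(with_hydrogens=True):
    """Idealized Watson–Crick G–C pair: three donor–acceptor contacts
    (G:N1–C:N3, G:N2–C:O2, C:N4–G:O6) at ~2.9 Å, hydrogens on the line."""
    g_atoms = [
        ("N1", "N", [0.0, 0.0, 0.0]),
        ("N2", "N", [0.0, -2.3, 0.0]),
        ("O6", "O", [0.0, 2.3, 0.0]),
        ("C2", "C", [-0.7, -1.2, 0.0]),  # ring carbon, no role
    ]
    c_atoms = [
        ("N3", "N", [2.9, 0.0, 0.0]),
        ("O2", "O", [2.9, -2.3, 0.0]),
        ("N4", "N", [2.9, 2.3, 0.0]),
        ("C5", "C", [3.6, 1.2, 0.0]),
    ]
    if with_hydrogens:
        g_atoms += [("H1", "H", [1.0, 0.0, 0.0]),
                    ("H21", "H", [1.0, -2.3, 0.0])]
        c_atoms += [("H41", "H", [1.9, 2.3, 0.0])]
    g = _res("A", 1, "G", "nucleotide", g_atoms)
    c = _res("A", 12, "C", "nucleotide", c_atoms)
    return StructureModel([g, c])


def test_watson_crick_pair_three_hbonds():
    model = _wc_gc_pair()
    hbonds = find_hbonds(model)
    pairs = {frozenset(rec.atom_names) for rec in hbonds}
    assert pairs == {frozenset({"N1", "N3"}), frozenset({"N2", "O2"}),
                     frozenset({"N4", "O6"})}
    # brute-force recount: every donor-acceptor pair satisfying both criteria
    assert len(hbonds) == 3


def test_hbond_distance_boundaries():
    def pair_model(da):
        g = _res("A", 1, "G", "nucleotide", [("N1", "N", [0, 0, 0])])
        c = _res("A", 3, "C", "nucleotide", [("N3", "N", [da, 0, 0])])
        return StructureModel([g, c])

    assert len(find_hbonds(pair_model(3.3))) == 1
    assert len(find_hbonds(pair_model(3.35))) == 0  # strict inequality


def test_explicit_hydrogen_criterion():
    """With a deposited hydrogen, H–A ≥ 2.7 Å vetoes the bond even when
    the donor–acceptor distance qualifies."""
    g = _res("A", 1, "G", "nucleotide",
             [("N1", "N", [0.0, 0.0, 0.0]),
              ("H1", "H", [-0.5, 0.87, 0.0])])  # points away from acceptor
    c = _res("A", 3, "C", "nucleotide", [("N3", "N", [3.2, 0.0, 0.0])])
    assert len(find_hbonds(StructureModel([g, c]))) == 0


def test_vdw_contacts_and_exclusions():
    model = _wc_gc_pair()
    hbonds = find_hbonds(model)
    vdw = find_vdw(model, hbonds=hbonds)
    hbond_pairs = {rec.pair_key for rec in hbonds}
    assert all(rec.pair_key not in hbond_pairs for rec in vdw)

    def two_atoms(d):
        a = _res("A", 1, "G", "nucleotide", [("C8", "C", [0, 0, 0])])
        b = _res("A", 5, "U", "nucleotide", [("C5", "C", [d, 0, 0])])
        return StructureModel([a, b])

    assert len(find_vdw(two_atoms(3.5), hbonds=[])) == 1
    assert len(find_vdw(two_atoms(3.9), hbonds=[])) == 0  # strict

    # backbone O3'(i)–P(i+1) covalent linkage is not a contact
    a = _res("A", 1, "G", "nucleotide", [("O3'", "O", [0, 0, 0])])
    b = _res("A", 2, "C", "nucleotide", [("P", "P", [1.6, 0, 0])])
    assert len(find_vdw(StructureModel([a, b]), hbonds=[])) == 0


def _record(kinds, names, groups):
    return ContactRecord(
        atom_names=("X", "Y"), residue_ids=(("A", 1, ""), ("A", 2, "")),
        residue_names=names, residue_kinds=kinds, groups=groups,
        contact_type="hbond", distance=3.0)


def test_categorize():
    assert categorize(_record(("nucleotide", "nucleotide"), ("A", "U"),
                              ("base", "base"))) == "BB"
    assert categorize(_record(("nucleotide", "nucleotide"), ("G", "C"),
                              ("ribose", "phosphate"))) == "PR"
    assert categorize(_record(("nucleotide", "nucleotide"), ("G", "C"),
                              ("ribose", "base"))) == "RB"
    assert categorize(_record(("nucleotide", "amino_acid"), ("G", "ARG"),
                              ("ribose", "charged"))) == "charged"
    assert categorize(_record(("ligand", "nucleotide"), ("LIG", "G"),
                              ("ligand", "base"))) == "ligand-base"
    assert categorize(_record(("ligand", "nucleotide"), ("LIG", "G"),
                              ("ligand", "phosphate"))) == "ligand-backbone"


def test_summarize_percentages():
    records = (
        [_record(("nucleotide",) * 2, ("A", "U"), ("base", "base"))] * 2
        + [_record(("nucleotide",) * 2, ("G", "C"), ("ribose", "ribose"))] * 2
    )
    summary = summarize(records)
    assert summary.counts["hbond"] == {"BB": 2, "RR": 2}
    assert summary.percentages["hbond"]["BB"] == pytest.approx(50.0)
    assert sum(summary.percentages["hbond"].values()) == pytest.approx(100.0)

    with pytest.warns(UserWarning, match="no categorizable"):
        empty = summarize([])
    assert empty.counts == {"hbond": {}, "vdw": {}}


def test_summary_matches_tally_oracle(ring_template):
    """Percentages on a real synthetic model agree with an independent
    brute-force recount of the categorized records."""
    hbonds = find_hbonds(ring_template)
    vdw = find_vdw(ring_template, hbonds=hbonds)
    records = hbonds + vdw
    assert records, "ring fixture should produce contacts"
    summary = summarize(records)
    for ctype in ("hbond", "vdw"):
        tally: dict[str, int] = {}
        for rec in records:
            if rec.contact_type != ctype:
                continue
            cat = categorize(rec)
            if cat != "other":
                tally[cat] = tally.get(cat, 0) + 1
        assert summary.counts[ctype] == tally
        total = sum(tally.values())
        if total:
            assert sum(summary.percentages[ctype].values()) == pytest.approx(
                100.0, abs=0.1)


def test_no_pair_is_both_hbond_and_vdw(small_ensemble):
    model = small_ensemble.models[1]
    hbonds = find_hbonds(model)
    vdw = find_vdw(model, hbonds=hbonds)
    assert not ({r.pair_key for r in hbonds} & {r.pair_key for r in vdw})
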