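"""Hydrogen-bond and vdW contact profile of a synthetic model.

Detects HBPLUS-style distance-criterion hydrogen bonds (D–A < 3.35 Å,
H–A < 2.7 Å when hydrogens are present) and van-der-Waals contacts
(< 3.9 Å, not H-bonded), then tallies them by chemical-group pair.
"""

from rpflex import find_hbonds, find_vdw, summarize
from rpflex.synthetic_fixtures import make_rna_template

model = make_rna_template(20)
hbonds = find_hbonds(model)
vdw = find_vdw(model, hbonds=hbonds)
print(f"hydrogen bonds: {len(hbonds)}, vdW contacts: {len(vdw)}")
summary = summarize(hbonds + vdw)
for ctype in ("hbond", "vdw"):
    print(f"{ctype}: ", {k: f"{v:.1f}%"
                         for k, v in summary.percentages[ctype].items()})
# Categories: BB base–base, RB ribose–base, PB phosphate–base,
# PR phosphate–ribose, RR ribose–ribose.  Percentages sum to 100 per type.
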