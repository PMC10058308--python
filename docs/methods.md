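# Methods

## Problem and model

NMR depositions of RNA contain several structural models of the same
molecule; the spread among those conformers is the experimental window onto
the molecule's flexibility. `rpflex` asks that question at the level of
*binding pockets*: detect the pockets of every model, recognize which
pockets across models are "the same" pocket, and quantify how much that
pocket's shape and position wander through the ensemble.

### Pocket detection (two-probe grid method)

Pockets are defined geometrically as the space a small probe (radius 3 Å)
can occupy but a large probe (radius 10 Å) cannot. On a cubic lattice this
is morphological closing of the atom occupancy with each probe ball,
implemented with exact Euclidean distance fields:

1. signed distance `dist(x)` to the nearest atom's van-der-Waals surface
   (per-element radii: C 1.70, N 1.55, O 1.52, P 1.80, S 1.80, else 1.60 Å);
2. probe-fit region for radius r: `dist > r`;
3. probe sweep: every voxel within r of a fit voxel (distance transform);
4. pocket voxels: swept by the small probe, not swept by the large probe,
   not inside an atom.

The pocket mask is split into 6-connected components; components below
`min_volume` (default 100 Å³) are grid noise and discarded. All models of an
entry share one lattice (1 Å spacing, origin at the floor of the
ensemble-wide bounding box), so cross-model overlap is a plain set
intersection.

A deliberate design choice: the exterior is *not* restricted to the
boundary-connected component. With boundary flood-fill, a cavity sealed
against both probes is "solvent-excluded" for both and cancels out of the
difference, so closed cavities — the cleanest analytically checkable test
case, and real binding sites in folded RNA — would be invisible. Pure
closing keeps them: a sealed cavity whose free radius lies between the two
probe radii is detected. For surface-connected pockets the two formulations
agree.

Surface area is exposed-face counting (`Ap` = exposed faces × h²). This
overestimates smooth surfaces by a staircase factor (≈1.5 for spheres, exact
for boxes); it is kept because it is deterministic and exactly
oracle-checkable, and because only *relative* topology changes enter the
flexibility score. An optional 2/3 correction (`staircase_correction=True`)
is available. Sphericity `ψ = π^(1/3)(6Vp)^(2/3)/Ap` and effective radius
`reff = 3Vp/Ap` follow from `Vp` and `Ap`.

### Similarity and grouping

`P_ij = |cells_i ∩ cells_j| / |cells_i|` — the fraction of reference pocket
i's voxels re-occupied by pocket j. P is asymmetric; both directions share
the overlap count (`P_ij·N_i = P_ji·N_j`). Pockets of the first structural
model serve as reference conformations; every other pocket joins the
reference with the highest similarity above the cutoff (0.25, strict
inequality; ties break to the lowest reference index). Pockets matching no
reference stay as leftover singletons. Groups need ≥ 3 members to be scored.

### Flexibility score

For a group's m×m similarity sub-matrix:

- `σ_i` — population (÷m) standard deviation of row i about its own row
  mean; `S` — mean of the σ_i; `P̄` — grand mean of the sub-matrix.
- `Γ` — mean over pockets of `|Ψ_i − π^(1/3)(6|V_i−V̄|)^(2/3)/(A_i−Ā)|`:
  each pocket's sphericity compared against the sphericity of its
  "difference pocket". Degenerate terms (|A_i−Ā| < 10⁻⁹ Å²) contribute
  |Ψ_i|; the volume difference enters by magnitude before the 2/3 power so
  the term is always real, while the area difference keeps its sign.
- `Q = (S/P̄)/Γ` by default.

Two places in this algebra are genuinely ambiguous and both readings are
implemented behind switches rather than guessed silently:

- `gamma_form`: `"sphericity"` (default) restores the `π^(1/3)·6^(2/3)`
  constant of the sphericity definition so the subtracted term is
  dimensionless like Ψ; `"literal"` uses `|V_i−V̄|^(2/3)/(6(A_i−Ā))` as the
  bare formula layout reads.
- `q_form`: `"quotient"` (default, the literal layout `(S/P̄)/Γ`) or
  `"product"` `(S/P̄)·Γ` (the prose reading that a larger topology change
  should raise, not lower, the score).

S = 0 (identical pockets) gives Q = 0 in every variant. Classes: rigidity
(Q < 0.30), intermediate (0.30 ≤ Q < 0.60), flexibility (Q ≥ 0.60).
Overlapping volume `Vg = V̄·P̄` stratifies groups into small (≤ 500 Å³),
medium (≤ 1500 Å³) and large (≤ 7200 Å³; beyond that a warning, still
"large").

### RMSF

Per nucleotide: root-mean-square displacement of a representative point
across the relevant models, against the model hosting the group's first
pocket (or a chosen model for whole-structure RMSF). The representative is
the unweighted heavy-atom centroid (`representative="com"`); C1′ is offered
because a fluctuation written per nucleotide does not dictate the reduction
from atoms, and a single backbone atom is the common alternative. No
superposition is applied — NMR models are deposited aligned; aligning
again would silently change the measured fluctuations.

Group RMSF averages over *overlapping nucleotides*: residues within 4 Å of
pocket voxels (≈ small-probe radius + heavy-atom vdW) in strictly more than
half of the group's pockets.

### Contact networks

Nodes are the lining nucleotides of the group's reference pocket (one shared
node set, so cross-model σ compares like with like; per-model lining sets
are available via `pocket_lining_nucleotides` directly). Edges join
residues with sequence separation ≥ 2 — covalent neighbours are always in
contact and carry no interaction signal; skipping them also matches how
shortest contact paths thread through folded RNA — whose closest heavy
atoms are strictly under 8 Å. Metrics: `<k> = 2L/N`, `<C>` (C_i = 0 for
degree < 2), diameter and average path length on the largest connected
component (infinite distances would poison the standard deviations; a flag
records when truncation happened). Population σ across the group's models,
multiplied by Q, gives the combined scores.

### Interactions

Hydrogen bonds use distance criteria only: donor–acceptor < 3.35 Å, plus
hydrogen–acceptor < 2.7 Å whenever an explicit hydrogen is bonded to the
donor (< 1.3 Å). HBPLUS additionally applies angular criteria; enforcing
only distances is a documented divergence. Donor/acceptor dictionaries ship
as an editable JSON data file (`rpflex/data/hbond_tables.json`). vdW
contacts: heavy-atom pairs < 3.9 Å, not hydrogen-bonded, not covalent
(backbone O3′–P and peptide C–N excluded). Categories: BB/RB/PB/PR/RR
within RNA (phosphate–phosphate pairs fall outside the five-category scheme
and are dropped from percentages), amino-acid category (charged/polar/
hydrophobic) for RNA–protein, ligand–base vs ligand–backbone for
RNA–ligand. The pipeline counts contacts per structural model and
aggregates over a group's members.

## Synthetic data

`synthetic_fixtures` generates every input class the pipeline needs:

- digitized spheres/boxes with analytic volumes (voxel-metric oracles);
- cavity shells: carbon atoms on a lattice shell whose inner vdW surface
  bounds a free sphere of the stated radius — detection ground truth;
- a ring-shaped RNA template (default 20 nt, backbone circle with bases
  pointing inward) whose axial channel is a guaranteed pocket;
- perturbed ensembles: model 1 is the template, later models displace each
  nucleotide rigidly by i.i.d. zero-mean Gaussian vectors of scale `s` Å
  per coordinate, so nucleotide RMSF has the closed form
  `(s/√m)·χ_{3(m−1)}`;
- toy graphs with hand-computable metrics.

What the generator does *not* emulate: base pairing and stacking, backbone
connectivity constraints (residues move independently), realistic torsions,
protein partners, or correlated collective motions. A green test therefore
establishes the *computational* correctness of each stage and the expected
monotone response of S, Q and RMSF to conformational spread — not that the
score reproduces values measured on deposited NMR ensembles. The default
amplitude `s = 0.5 Å` sits in the middle of the per-residue spread typical
of well-converged NMR ensembles (tenths of an Å to a few Å).

## Numerical choices

- Distance comparisons at stated cutoffs are strict (`< 8 Å`, `< 3.35 Å`,
  `< 3.9 Å`, `P_ij > 0.25`) per their definitions; the Vg bin bounds are
  upper-inclusive (`Vg = 500` is "small").
- Pocket ordering within a model: decreasing volume, ties by
  lexicographically smallest cell — ordering only affects labels.
- Modified nucleotides map to their parent base via a name table; unknown
  residues become `kind="other"` and are excluded from group statistics.
- Alternate locations: Biopython's default (highest-occupancy) conformer.
- Γ's ε-guard: 10⁻⁹ Å² on |A_i − Ā|.
- All randomness flows through `numpy.random.default_rng(seed)`; fixtures
  are byte-reproducible from (parameters, seed).

## Known limitations

- The detector is a reconstruction of the discrete two-probe volume method;
  the reference implementation's internal parameters (grid anchoring, area
  estimator, noise filtering) are unpublished, so pocket counts and derived
  Q values on deposited entries can differ in detail even when the
  methodology matches.
- Grid-level staircase noise produces single-voxel slivers at `min_volume=0`;
  the set-inclusion monotonicity of the solvent-excluded regions holds for
  the continuous geometry and for filtered pockets, not voxel-by-voxel.
- Disconnected contact networks report path metrics on the largest
  component only.
- Only single-RNA-chain entries (optionally with one ligand or one protein
  chain) are in scope; multi-chain RNA is not handled.
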