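"""End-to-end orchestration: detect → group → score → RMSF → network → contacts.

:func:`run_entry` runs every stage on one ensemble and returns an
:class:`EntryReport` that is fully determined by the input and the
configuration (identical runs produce byte-identical JSON).  Groups with
fewer than three member pockets are reported as invalid and excluded from
scoring, mirroring the dataset-level filter of the method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .contact_network import build_network, ensemble_network_flexibility
from .ensemble_rmsf import (
    group_rmsf,
    overlapping_nucleotides,
    pocket_lining_nucleotides,
    structure_rmsf,
)
from .flexibility_score import score_group
from .interactions import find_hbonds, find_vdw, summarize
from .pocket_detect import compute_metrics, detect_pockets
from .pocket_similarity import build_matrix, group_pockets
from .structure_io import Ensemble

__all__ = ["PipelineConfig", "EntryReport", "run_entry"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable parameter of the pipeline, with method defaults."""

    large_probe: float = 10.0  # Å
    small_probe: float = 3.0  # Å
    spacing: float = 1.0  # Å
    min_volume: float = 100.0  # Å³
    similarity_cutoff: float = 0.25
    min_group_members: int = 3
    gamma_form: str = "sphericity"  # or "literal"
    q_form: str = "quotient"  # or "product"
    lining_cutoff: float = 4.0  # Å
    network_cutoff: float = 8.0  # Å
    min_seq_sep: int = 2
    representative: str = "com"  # or "C1prime"
    include_ligand_occupancy: bool = False


@dataclass
class EntryReport:
    entry_id: str
    n_models: int
    rna_chain: str
    partner_kind: str
    config: dict
    pockets: list[dict]
    groups: list[dict]
    structure_rmsf: dict
    errors: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def run_entry(
    ensemble: Ensemble,
    config: PipelineConfig | None = None,
) -> EntryReport:
    """Run the full pocket-flexibility pipeline on one ensemble."""
    cfg = config or PipelineConfig()

    # global lattice origin: floor of the ensemble-wide bounding box
    all_coords = np.vstack(
        [a.coords for m in ensemble.models for a in m.atoms])
    origin = tuple(np.floor(all_coords.min(axis=0)))

    all_pockets = []
    for midx, model in enumerate(ensemble.models, start=1):
        all_pockets.extend(
            detect_pockets(
                model,
                large_probe=cfg.large_probe,
                small_probe=cfg.small_probe,
                spacing=cfg.spacing,
                min_volume=cfg.min_volume,
                model_index=midx,
                origin=origin,
                include_ligand_occupancy=cfg.include_ligand_occupancy,
            )
        )

    pockets_out = []
    metrics_by_label = {}
    for pocket in all_pockets:
        mt = compute_metrics(pocket)
        metrics_by_label[pocket.label] = mt
        pockets_out.append({
            "label": pocket.label,
            "model": pocket.model_index,
            "n_cells": pocket.n_cells,
            "Vp": _round(mt.Vp),
            "Ap": _round(mt.Ap),
            "psi": _round(mt.psi),
            "reff": _round(mt.reff),
            "centroid": [_round(c) for c in mt.centroid],
        })

    groups_out: list[dict] = []
    errors: dict[str, str] = {}
    if all_pockets:
        matrix = build_matrix(all_pockets)
        groups = group_pockets(
            matrix,
            cutoff=cfg.similarity_cutoff,
            entry_id=ensemble.entry_id,
            min_members=cfg.min_group_members,
        )
        label_to_idx = {lab: k for k, lab in enumerate(matrix.labels)}
        for group in groups:
            entry: dict = {
                "group_label": group.group_label,
                "reference": group.reference,
                "members": group.member_labels,
                "m": group.m,
                "valid": group.valid,
            }
            if not group.valid:
                groups_out.append(entry)
                continue
            try:
                idx = [label_to_idx[lab] for lab in group.member_labels]
                sub = matrix.P[np.ix_(idx, idx)]
                metrics = [metrics_by_label[lab]
                           for lab in group.member_labels]
                flex = score_group(sub, metrics,
                                   gamma_form=cfg.gamma_form,
                                   q_form=cfg.q_form)
                entry["flexibility"] = {
                    k: (_round(v) if isinstance(v, float)
                        else [_round(x) for x in v] if isinstance(v, list)
                        else v)
                    for k, v in asdict(flex).items()
                }

                rmsf = group_rmsf(group, ensemble,
                                  representative=cfg.representative,
                                  contact_cutoff=cfg.lining_cutoff)
                entry["rmsf"] = {
                    "overlapping_nucleotides":
                        [list(r) for r in rmsf.overlapping_nucleotides],
                    "per_nucleotide":
                        {"|".join(map(str, rid)): _round(v)
                         for rid, v in rmsf.per_nucleotide_rmsf.items()},
                    "mean_rmsf": _round(rmsf.mean_rmsf),
                    "reference_model": rmsf.reference_model,
                }

                # node set: lining nucleotides of the reference pocket,
                # evaluated in each member's model
                ref_pocket = next(p for p in group.members
                                  if p.label == group.reference)
                ref_model = ensemble.models[ref_pocket.model_index - 1]
                nodes = sorted(pocket_lining_nucleotides(
                    ref_pocket, ref_model, cfg.lining_cutoff,
                    ensemble.rna_chain))
                nets = [
                    build_network(
                        ensemble.models[p.model_index - 1], nodes,
                        cutoff=cfg.network_cutoff,
                        min_seq_sep=cfg.min_seq_sep,
                        model_index=p.model_index)
                    for p in group.members
                ]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    netflex = ensemble_network_flexibility(nets, flex.Q)
                entry["network"] = {
                    "nodes": [list(r) for r in nodes],
                    "sigma": {k: _round(v)
                              for k, v in netflex.sigma.items()},
                    "combined": {k: _round(v)
                                 for k, v in netflex.combined.items()},
                    "disconnected_models": netflex.disconnected_models,
                }

                scope = set(overlapping_nucleotides(
                    group, ensemble, cfg.lining_cutoff))
                hb_counts: dict[str, dict[str, int]] = {}
                for pocket in group.members:
                    model = ensemble.models[pocket.model_index - 1]
                    hbonds = find_hbonds(model)
                    vdw = find_vdw(model, hbonds=hbonds)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        summary = summarize(hbonds + vdw, scope=scope)
                    for ctype, cats in summary.counts.items():
                        slot = hb_counts.setdefault(ctype, {})
                        for cat, cnt in cats.items():
                            slot[cat] = slot.get(cat, 0) + cnt
                totals = {
                    ctype: sum(cats.values())
                    for ctype, cats in hb_counts.items()
                }
                entry["interactions"] = {
                    "counts": hb_counts,
                    "percentages": {
                        ctype: {cat: _round(100.0 * cnt / totals[ctype], 2)
                                for cat, cnt in cats.items()}
                        for ctype, cats in hb_counts.items() if totals[ctype]
                    },
                }
            except Exception as exc:  # noqa: BLE001 - partial reports allowed
                errors[group.group_label] = f"{type(exc).__name__}: {exc}"
            groups_out.append(entry)

    if ensemble.n_models >= 2:
        srmsf = structure_rmsf(ensemble,
                               representative=cfg.representative)
        structure_out = {
            "per_nucleotide": {"|".join(map(str, rid)): _round(v)
                               for rid, v in srmsf.per_nucleotide_rmsf.items()},
            "mean_rmsf": _round(srmsf.mean_rmsf),
            "reference_model": srmsf.reference_model,
        }
    else:
        structure_out = {}

    return EntryReport(
        entry_id=ensemble.entry_id,
        n_models=ensemble.n_models,
        rna_chain=ensemble.rna_chain,
        partner_kind=ensemble.partner_kind,
        config=asdict(cfg),
        pockets=pockets_out,
        groups=groups_out,
        structure_rmsf=structure_out,
        errors=errors,
    )
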