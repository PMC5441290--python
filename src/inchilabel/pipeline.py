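"""End-to-end labeling of one connected molecule.

This is the single-component path: compute the standard InChI, verify the
graph correspondence, label heavy atoms from canonical numbers, rank
hydrogens center by center, and assemble the complete assignment.  Mixture
records are delaminated into components first (see :mod:`.mixtures`) so
that a component's labels are identical whether it is analyzed alone or
inside a mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

from .heavy_labeling import LabelAssignment, assign_heavy_labels
from .hydrogen_labeling import (
    HydrogenRanking,
    amide_rank,
    assign_hydrogen_labels,
    break_symmetry,
    is_primary_amide_nitrogen,
    perturb_and_sign,
)
from .inchi_engine import InChIEngine, InChIRecord, compute_inchi, default_engine
from .molgraph import MolGraph

__all__ = ["ComponentResult", "label_component"]


@dataclass
class ComponentResult:
    """Everything the pipeline derives for one connected molecule."""

    mol: MolGraph
    record: InChIRecord
    labels: LabelAssignment
    rankings: list[HydrogenRanking]
    engine_calls: int


def label_component(
    mol: MolGraph, engine: InChIEngine | None = None
) -> ComponentResult:
    """Run the full labeling protocol on a connected molecule."""
    engine = engine or default_engine
    calls_before = engine.calls
    rec = compute_inchi(mol, engine)
    if rec.n_components != 1:
        raise ValueError(
            "label_component expects a connected molecule; "
            "use mixtures.process_record for multi-component input"
        )
    partial = assign_heavy_labels(mol, rec)
    rankings: list[HydrogenRanking] = []
    pending: list[HydrogenRanking] = []
    for center in mol.heavy_indices():
        n_h = len(mol.hydrogen_neighbors(center))
        if n_h < 2:
            continue
        if is_primary_amide_nitrogen(mol, center):
            rankings.append(amide_rank(mol, center))
        else:
            pending.append(perturb_and_sign(mol, center, engine))
    rankings.extend(break_symmetry(mol, pending, engine))
    labels = assign_hydrogen_labels(mol, rec, partial, rankings)
    return ComponentResult(
        mol=mol,
        record=rec,
        labels=labels,
        rankings=rankings,
        engine_calls=engine.calls - calls_before,
    )
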