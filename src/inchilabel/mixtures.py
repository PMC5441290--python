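"""Mixture delamination and multi-record processing.

A disconnected structure record carries several molecules in one file.  The
standard InChI of such a record concatenates per-component layer blocks in
its own canonical component order; delamination splits those blocks, matches
each to a connected component of the input graph through the AuxInfo
numbering, and labels every component with the ordinary single-molecule
pipeline.  Global labels then get a ``c<ordinal>.`` prefix, so a component's
internal labels are identical whether it is analyzed alone or inside a
mixture — the combined identifier (full-record InChI plus ordered component
blocks) specifies both the constituents and their arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .heavy_labeling import LabelAssignment
from .inchi_engine import InChIEngine, InChIRecord, compute_inchi, default_engine
from .molgraph import MolGraph, connected_components
from .pipeline import ComponentResult, label_component

__all__ = [
    "ComponentBlock",
    "RecordResult",
    "DelaminationError",
    "delaminate",
    "label_mixture",
    "process_record",
    "process_multirecord",
]


class DelaminationError(RuntimeError):
    """Component count or identity mismatch between graph and identifier."""


@dataclass
class ComponentBlock:
    """One molecule of a mixture: its atoms, identifier and label fragment."""

    ordinal: int  # 1-based position in the InChI component order
    atom_indices: set[int]  # original indices, hydrogens included
    component_inchi: str
    result: ComponentResult
    old2new: dict[int, int]
    multiplicity_group: int = 0

    @property
    def labels(self) -> LabelAssignment:
        return self.result.labels


@dataclass
class RecordResult:
    """Full-record outcome: record-level InChI plus per-component blocks."""

    mol: MolGraph
    record: InChIRecord
    blocks: list[ComponentBlock]
    labels: LabelAssignment = field(default_factory=LabelAssignment)


def delaminate(
    mol: MolGraph, rec: InChIRecord, engine: InChIEngine | None = None
) -> list[ComponentBlock]:
    """Split a record into per-molecule blocks in InChI component order.

    Components are identified from the formula-layer '.' split (multipliers
    expanded); each is matched to a connected component of the input graph
    via the canonical-numbering map and labeled standalone.  Identical
    components share a multiplicity group, their ordinal slots re-sorted by
    smallest original atom index so the choice is deterministic.
    """
    engine = engine or default_engine
    comps = connected_components(mol)
    if len(comps) != rec.n_components:
        raise DelaminationError(
            f"graph has {len(comps)} components, identifier has {rec.n_components}"
        )
    blocks: list[ComponentBlock] = []
    claimed: set[int] = set()
    for k in range(rec.n_components):
        heavy = set(rec.canonical_map[k].values())
        match = None
        for ci, comp in enumerate(comps):
            if ci not in claimed and heavy <= set(comp):
                match = ci
                break
        if match is None:
            raise DelaminationError(
                f"InChI component {k + 1} matches no unclaimed graph component"
            )
        claimed.add(match)
        sub, old2new = mol.subgraph(comps[match])
        result = label_component(sub, engine)
        expected_formula = rec.formula[k]
        if result.record.formula != [expected_formula]:
            raise DelaminationError(
                f"component {k + 1}: standalone formula "
                f"{result.record.formula[0]} != record formula {expected_formula}"
            )
        blocks.append(
            ComponentBlock(
                ordinal=k + 1,
                atom_indices=set(comps[match]),
                component_inchi=result.record.inchi,
                result=result,
                old2new=old2new,
            )
        )
    # multiplicity groups + deterministic ordinal order among identical copies
    by_inchi: dict[str, list[ComponentBlock]] = {}
    for b in blocks:
        by_inchi.setdefault(b.component_inchi, []).append(b)
    for gid, (_, group) in enumerate(sorted(by_inchi.items()), start=1):
        slots = sorted(b.ordinal for b in group)
        for b, slot in zip(sorted(group, key=lambda b: min(b.atom_indices)), slots):
            b.ordinal = slot
            b.multiplicity_group = gid
    blocks.sort(key=lambda b: b.ordinal)
    return blocks


def label_mixture(blocks: list[ComponentBlock]) -> LabelAssignment:
    """Combine per-component assignments into one global map.

    Labels get a ``c<ordinal>.`` prefix when the record holds more than one
    component; single-component records keep plain labels.  Identical
    components are mutually interchangeable at block level and recorded in
    ``interchangeable_blocks``.
    """
    global_labels = LabelAssignment()
    multi = len(blocks) > 1
    for block in blocks:
        prefix = f"c{block.ordinal}." if multi else ""
        new2old = {v: k for k, v in block.old2new.items()}
        for sub_index, label in block.labels.forward.items():
            global_labels.add(
                new2old[sub_index], f"{prefix}{label}", component=block.ordinal
            )
        global_labels.merge_interchangeable(
            [{f"{prefix}{l}" for l in s} for s in block.labels.interchangeable_sets]
        )
    groups: dict[int, list[int]] = {}
    for b in blocks:
        groups.setdefault(b.multiplicity_group, []).append(b.ordinal)
    global_labels.interchangeable_blocks = [
        tuple(sorted(v)) for v in groups.values() if len(v) > 1
    ]
    return global_labels


def process_record(
    mol: MolGraph, engine: InChIEngine | None = None
) -> RecordResult:
    """Label one structure record, delaminating mixtures as needed."""
    engine = engine or default_engine
    rec = compute_inchi(mol, engine)
    blocks = delaminate(mol, rec, engine)
    labels = label_mixture(blocks)
    return RecordResult(mol=mol, record=rec, blocks=blocks, labels=labels)


def process_multirecord(
    mols: list[MolGraph], engine: InChIEngine | None = None
) -> list[RecordResult | Exception]:
    """Process each record independently (e.g. tautomeric states).

    Output preserves record order; a failing record contributes its error
    while the remaining records are still processed.
    """
    out: list[RecordResult | Exception] = []
    for m in mols:
        try:
            out.append(process_record(m, engine))
        except Exception as exc:  # reported per record
            out.append(exc)
    return out
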