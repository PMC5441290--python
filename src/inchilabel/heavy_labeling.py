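"""Heavy-atom labels from InChI canonical numbers.

A heavy atom with canonical number ``n`` and element ``E`` is labeled
``E<n>`` (the third canonical atom of ethanol, an oxygen, becomes ``O3``).
Before any label is written, the connection graph encoded in the /c layer is
relabeled through the AuxInfo canonical-numbering map and compared
edge-for-edge against the input heavy-atom graph; a mismatch means the
engine and the parser disagree about the molecule and is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .inchi_engine import InChIRecord, connection_graph
from .molgraph import MolGraph, connected_components

__all__ = ["LabelAssignment", "CorrespondenceError", "verify_correspondence",
           "assign_heavy_labels"]


class CorrespondenceError(RuntimeError):
    """Input graph and InChI-derived graph disagree; never proceed silently."""


_LABEL_KEY_CACHE: dict[str, tuple] = {}


@dataclass
class LabelAssignment:
    """Bidirectional map between input atom indices and unique labels.

    ``interchangeable_sets`` lists maximal groups of labels that are mutually
    exchangeable (homotopic hydrogens, symmetry-equivalent positions); atoms
    outside every set are guaranteed to keep their label under any
    renumbering of the input file.  ``interchangeable_blocks`` groups the
    ordinals of identical mixture components.
    """

    forward: dict[int, str] = field(default_factory=dict)
    inverse: dict[str, int] = field(default_factory=dict)
    component_of: dict[int, int] = field(default_factory=dict)
    interchangeable_sets: list[frozenset[str]] = field(default_factory=list)
    interchangeable_blocks: list[tuple[int, ...]] = field(default_factory=list)

    def add(self, index: int, label: str, component: int = 1) -> None:
        if index in self.forward:
            raise ValueError(f"atom {index} labeled twice")
        if label in self.inverse:
            raise ValueError(f"duplicate label {label!r}")
        self.forward[index] = label
        self.inverse[label] = index
        self.component_of[index] = component

    @staticmethod
    def sort_key(label: str):
        """Deterministic label ordering: component ordinal, then number."""
        key = _LABEL_KEY_CACHE.get(label)
        if key is None:
            comp = 0
            body = label
            if body.startswith("c") and "." in body:
                prefix, body = body.split(".", 1)
                comp = int(prefix[1:])
            alpha = body.rstrip("0123456789")
            num = int(body[len(alpha):]) if body[len(alpha):] else 0
            key = (comp, num, alpha)
            _LABEL_KEY_CACHE[label] = key
        return key

    def merge_interchangeable(self, new_sets) -> None:
        """Add label sets, merging transitively-overlapping groups."""
        pool = [set(s) for s in self.interchangeable_sets]
        pool.extend(set(s) for s in new_sets if len(s) > 1)
        merged: list[set[str]] = []
        for s in pool:
            hits = [m for m in merged if m & s]
            for m in hits:
                s |= m
                merged.remove(m)
            merged.append(s)
        self.interchangeable_sets = sorted(
            (frozenset(m) for m in merged),
            key=lambda m: min(self.sort_key(l) for l in m),
        )

    def interchangeable_labels(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.interchangeable_sets:
            out |= s
        return frozenset(out)


def _input_heavy_edges(mol: MolGraph, atoms: set[int]) -> set[frozenset[int]]:
    heavy = {i for i in atoms if mol.atom(i).element != "H"}
    return {
        b.key
        for b in mol.bonds
        if b.a in heavy and b.b in heavy
    }


def verify_correspondence(mol: MolGraph, rec: InChIRecord) -> list[dict[int, int]]:
    """Check that the /c graph under the canonical map equals the input graph.

    For every component: each canonical position's element must match the
    formula-layer ordering, and the /c edges relabeled through the canonical
    map must equal the input heavy-atom subgraph.  Returns the per-component
    canonical -> input maps on success.
    """
    comps = connected_components(mol)
    heavy_total = len(mol.heavy_indices())
    mapped = [rec.canonical_map[k] for k in range(rec.n_components)]
    n_mapped = sum(len(m) for m in mapped)
    if n_mapped != heavy_total:
        raise CorrespondenceError(
            f"canonical map covers {n_mapped} heavy atoms, input has {heavy_total}"
        )
    if len(comps) != rec.n_components:
        raise CorrespondenceError(
            f"input has {len(comps)} connected components, InChI {rec.n_components}"
        )
    for k in range(rec.n_components):
        cmap = mapped[k]
        elements = rec.component_elements(k)
        for canon, orig in cmap.items():
            actual = mol.atom(orig).element
            if actual != elements[canon - 1]:
                raise CorrespondenceError(
                    f"component {k + 1}: canonical atom {canon} is "
                    f"{elements[canon - 1]} in the formula but {actual} in the input"
                )
        comp_atoms = None
        for comp in comps:
            if set(cmap.values()) <= set(comp):
                comp_atoms = set(comp)
                break
        if comp_atoms is None:
            raise CorrespondenceError(
                f"component {k + 1}: canonical atoms span multiple input components"
            )
        cgraph = connection_graph(rec, k)
        inchi_edges = {
            frozenset((cmap[a], cmap[b])) for a, b in cgraph.edges
        }
        if inchi_edges != _input_heavy_edges(mol, comp_atoms):
            raise CorrespondenceError(
                f"component {k + 1}: /c connection graph does not match the "
                "input heavy-atom graph under the canonical numbering"
            )
    return mapped


def assign_heavy_labels(mol: MolGraph, rec: InChIRecord) -> LabelAssignment:
    """Label heavy atoms ``E<n>`` from their canonical numbers.

    Numbering restarts per component (as in InChI); callers labeling
    mixtures add a component prefix afterwards, so labels stay identical
    whether a component is analyzed alone or inside a mixture.
    """
    mapped = verify_correspondence(mol, rec)
    labels = LabelAssignment()
    for k, cmap in enumerate(mapped):
        elements = rec.component_elements(k)
        prefix = f"c{k + 1}." if rec.n_components > 1 else ""
        for canon in sorted(cmap):
            labels.add(
                cmap[canon], f"{prefix}{elements[canon - 1]}{canon}", component=k + 1
            )
    return labels
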