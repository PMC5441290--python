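"""Standard-InChI computation and layer/AuxInfo parsing.

The reference InChI implementation (bundled with rdkit) is driven through a
deliberately narrow interface: a V2000 molblock goes in, the standard InChI
string and its auxiliary information come out.  Everything this package
derives from the identifier — canonical atom numbers, per-component layers,
the /c connection graph, constitutional equivalence classes — is parsed from
those two strings, never from the toolkit's own molecule object.

``orbit_partition`` provides an engine-independent symmetry substrate: an
iterated invariant-refinement partition of the atoms that over-approximates
the automorphism orbits of the molecular graph (exact on all shipped
fixtures, backed by an exhaustive search oracle in the tests).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx

from .molgraph import MolGraph, write_molblock

__all__ = [
    "InChIEngine",
    "InChIError",
    "InChIRecord",
    "OrbitPartition",
    "compute_inchi",
    "parse_layers",
    "split_components",
    "parse_formula",
    "formula_heavy_elements",
    "connection_graph",
    "parse_connection_layer",
    "orbit_partition",
    "default_engine",
]

logger = logging.getLogger(__name__)


class InChIError(RuntimeError):
    """The InChI engine rejected the structure or produced no output."""


class InChIEngine:
    """Thin wrapper around the reference InChI implementation.

    Counts every invocation (``calls``); the iterative hydrogen-labeling
    protocol makes engine calls the hot path and the count is asserted
    against a documented bound in the tests.
    """

    def __init__(self) -> None:
        self.calls = 0
        from rdkit import RDLogger

        # The engine emits advisory notes for every isotopomer variant;
        # route rdkit's logging away from stderr.
        RDLogger.DisableLog("rdApp.*")

    def run(self, molblock: str) -> tuple[str, str]:
        """molblock text in -> (standard InChI, AuxInfo) out."""
        from rdkit.Chem.inchi import MolBlockToInchiAndAuxInfo

        self.calls += 1
        try:
            inchi, auxinfo = MolBlockToInchiAndAuxInfo(molblock, treatWarningAsError=False)
        except Exception as exc:  # engine-level rejection
            raise InChIError(f"InChI engine failure: {exc}") from exc
        if not inchi:
            raise InChIError("InChI engine produced no identifier for the input")
        return inchi, auxinfo or ""


default_engine = InChIEngine()


# ---------------------------------------------------------------------------
# Layer parsing


_MULT = re.compile(r"^(\d+)\*(.*)$")
_FORMULA_MULT = re.compile(r"^(\d+)([A-Z].*)$")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Layers whose text splits per component on ';'
_SPLITTABLE = {"c", "h", "q", "p", "b", "t", "i"}


def split_components(layer: str, n_components: int) -> list[str]:
    """Split a layer on ';' and expand "k*seg" multipliers."""
    out: list[str] = []
    for seg in layer.split(";"):
        m = _MULT.match(seg)
        if m:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(seg)
    if len(out) != n_components:
        raise InChIError(
            f"layer {layer!r} expands to {len(out)} components, expected {n_components}"
        )
    return out


def _expand_formula(formula: str) -> list[str]:
    comps: list[str] = []
    for seg in formula.split("."):
        m = _FORMULA_MULT.match(seg)
        if m and not seg[0].isalpha():
            comps.extend([m.group(2)] * int(m.group(1)))
        else:
            comps.append(seg)
    return comps


def parse_formula(formula: str) -> dict[str, int]:
    """Element counts of one component formula like ``C6H13NO2``."""
    counts: dict[str, int] = {}
    for el, num in _FORMULA_TOKEN.findall(formula):
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def formula_heavy_elements(formula: str) -> list[str]:
    """Element of each canonical number, derived from the formula layer.

    InChI numbers the heavy atoms of a component in formula order (carbons
    first when present, remaining elements alphabetically); hydrogens are
    not canonically numbered.
    """
    seq: list[str] = []
    for el, num in _FORMULA_TOKEN.findall(formula):
        if el == "H":
            continue
        seq.extend([el] * (int(num) if num else 1))
    return seq


def parse_layers(inchi: str) -> tuple[dict[str, str], int]:
    """Split a standard InChI into its layer map and component count.

    Returns an ordered tag -> text map.  The formula sits under ``formula``;
    stereo/isotope sub-layers that follow the /i layer are stored with an
    ``i.`` prefix (e.g. ``i.t``) so that the main and isotopic stereo layers
    never collide.
    """
    if not inchi.startswith("InChI=1S/"):
        raise InChIError(f"not a standard InChI string: {inchi[:20]!r}...")
    body = inchi[len("InChI=1S/") :]
    segments = body.split("/")
    layers: dict[str, str] = {"formula": segments[0]}
    in_isotopic = False
    for seg in segments[1:]:
        if not seg:
            continue
        tag, value = seg[0], seg[1:]
        if tag == "i":
            in_isotopic = True
        key = f"i.{tag}" if in_isotopic and tag != "i" else tag
        if key in layers:
            raise InChIError(f"duplicate layer /{key} in {inchi!r}")
        layers[key] = value
    n_components = len(_expand_formula(layers["formula"]))
    return layers, n_components


# ---------------------------------------------------------------------------
# AuxInfo parsing


def _aux_segments(auxinfo: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for seg in auxinfo.split("/"):
        m = re.match(r"^([A-Za-z]+):(.*)$", seg)
        if m:
            out.setdefault(m.group(1), m.group(2))
    return out


def _parse_numbering(segment: str) -> list[list[int]]:
    comps: list[list[int]] = []
    for part in segment.split(";"):
        if part == "m":  # identical to the previous component
            comps.append(list(comps[-1]))
        elif part:
            comps.append([int(tok) for tok in part.split(",")])
        else:
            comps.append([])
    return comps


def _parse_equivalence(segment: str, n_components: int) -> list[list[set[int]]]:
    """Parse an /E: segment into per-component lists of canonical-number sets."""
    comps: list[list[set[int]]] = []
    for part in segment.split(";"):
        if part == "m":
            comps.append([set(s) for s in comps[-1]])
        elif part:
            m = _MULT.match(part)
            reps = 1
            if m:
                reps, part = int(m.group(1)), m.group(2)
            classes = [
                {int(tok) for tok in grp.split(",")}
                for grp in re.findall(r"\(([^)]*)\)", part)
            ]
            for _ in range(reps):
                comps.append([set(s) for s in classes])
        else:
            comps.append([])
    while len(comps) < n_components:
        comps.append([])
    return comps


# ---------------------------------------------------------------------------
# The identifier record


@dataclass
class InChIRecord:
    """Standard InChI plus parsed layers and the canonical-numbering map."""

    inchi: str
    auxinfo: str
    layers: dict[str, str]
    n_components: int
    formula: list[str]
    component_layers: list[dict[str, str]]
    canonical_map: list[dict[int, int]]  # per component: canonical -> input index
    equivalence: list[list[set[int]]] = field(default_factory=list)

    def component_elements(self, k: int) -> list[str]:
        return formula_heavy_elements(self.formula[k])


def _component_layer_maps(
    layers: dict[str, str], n_components: int, formula: list[str]
) -> list[dict[str, str]]:
    comp_layers: list[dict[str, str]] = [
        {"formula": formula[k]} for k in range(n_components)
    ]
    for tag, text in layers.items():
        if tag in _SPLITTABLE:
            for k, seg in enumerate(split_components(text, n_components)):
                if seg:
                    comp_layers[k][tag] = seg
    return comp_layers


def compute_inchi(mol: MolGraph, engine: InChIEngine | None = None) -> InChIRecord:
    """Compute the standard InChI of ``mol`` and parse it into a record.

    Deterministic: identical input bytes give identical output.  The
    canonical-numbering map is read from the AuxInfo original-numbering
    (``/N:``) sub-layer, superseded by ``/F:`` when the fixed-H numbering
    differs (logged).
    """
    engine = engine or default_engine
    inchi, auxinfo = engine.run(write_molblock(mol))
    layers, n_components = parse_layers(inchi)
    formula = _expand_formula(layers["formula"])
    aux = _aux_segments(auxinfo)
    if "N" not in aux:
        raise InChIError(f"AuxInfo lacks the /N: numbering sub-layer: {auxinfo!r}")
    numbering = _parse_numbering(aux["N"])
    if "F" in aux:
        logger.info("AuxInfo /F: fixed-H numbering present; superseding /N:")
        fixed = _parse_numbering(aux["F"])
        numbering = [
            fixed[k] if fixed[k] else numbering[k] for k in range(len(numbering))
        ]
    if len(numbering) != n_components:
        raise InChIError(
            f"AuxInfo lists {len(numbering)} components, formula has {n_components}"
        )
    canonical_map = [
        {canon: orig for canon, orig in enumerate(comp, start=1)}
        for comp in numbering
    ]
    equivalence = _parse_equivalence(aux.get("E", ""), n_components)
    comp_layers = _component_layer_maps(layers, n_components, formula)
    rec = InChIRecord(
        inchi=inchi,
        auxinfo=auxinfo,
        layers=layers,
        n_components=n_components,
        formula=formula,
        component_layers=comp_layers,
        canonical_map=canonical_map,
        equivalence=equivalence,
    )
    for k in range(n_components):
        expected = len(rec.component_elements(k))
        if expected != len(canonical_map[k]):
            raise InChIError(
                f"component {k + 1}: {len(canonical_map[k])} canonical atoms "
                f"in AuxInfo but formula {formula[k]} has {expected} heavy atoms"
            )
    return rec


# ---------------------------------------------------------------------------
# /c connection-layer graph


def parse_connection_layer(text: str) -> list[tuple[int, int]]:
    """Edges encoded by one component's /c layer.

    Grammar: numbers are canonical atoms, '-' chains them, parentheses open
    branches from the atom before them, ',' starts a sibling branch, and a
    number already seen closes a ring without moving the walk.
    """
    edges: list[tuple[int, int]] = []
    seen: set[int] = set()
    stack: list[int | None] = []
    current: int | None = None
    for tok in re.findall(r"\d+|[()\-,]", text):
        if tok == "(":
            stack.append(current)
        elif tok == ")":
            if not stack:
                raise InChIError(f"unbalanced ')' in /c layer {text!r}")
            current = stack.pop()
        elif tok == ",":
            if not stack:
                raise InChIError(f"',' outside branch in /c layer {text!r}")
            current = stack[-1]
        elif tok == "-":
            continue
        else:
            n = int(tok)
            if current is not None:
                edges.append((current, n))
            if n in seen:
                continue  # ring closure: the walk stays where it was
            seen.add(n)
            current = n
    if stack:
        raise InChIError(f"unbalanced '(' in /c layer {text!r}")
    return edges


def connection_graph(rec: InChIRecord, component: int = 0) -> nx.Graph:
    """Heavy-atom graph of one component, keyed by canonical numbers."""
    elements = rec.component_elements(component)
    g = nx.Graph()
    for canon, el in enumerate(elements, start=1):
        g.add_node(canon, element=el)
    text = rec.component_layers[component].get("c", "")
    for a, b in parse_connection_layer(text):
        if a not in g or b not in g:
            raise InChIError(
                f"/c layer references canonical atom outside formula: {a}-{b}"
            )
        g.add_edge(a, b)
    return g


# ---------------------------------------------------------------------------
# Invariant-refinement orbit partition


@dataclass(frozen=True)
class OrbitPartition:
    """Atom classes interchangeable under (an over-approximation of) the
    automorphism group, plus the number of refinement rounds used."""

    classes: tuple[frozenset[int], ...]
    refinement_rounds: int

    def class_of(self, index: int) -> frozenset[int]:
        for cls in self.classes:
            if index in cls:
                return cls
        raise KeyError(index)


def orbit_partition(mol: MolGraph) -> OrbitPartition:
    """Iterated invariant refinement to a fixpoint.

    Seed invariant: element, charge, isotope, degree, attached-H count.
    Refinement: the sorted multiset of neighbor classes.  Bond orders are
    ignored, matching InChI's bond-order-free canonical skeleton (the two
    Kekulé forms of a ring must not split an orbit).
    """
    neighbors = {a.index: mol.neighbors(a.index) for a in mol.atoms}
    color: dict[int, int] = {}
    seed = {}
    for a in mol.atoms:
        n_h = sum(1 for j in neighbors[a.index] if mol.atom(j).element == "H")
        seed[a.index] = (
            a.element,
            a.formal_charge,
            a.isotope_mass or 0,
            len(neighbors[a.index]),
            n_h,
        )
    palette = {v: i for i, v in enumerate(sorted(set(seed.values()), key=repr))}
    color = {i: palette[v] for i, v in seed.items()}
    rounds = 0
    while True:
        sig = {
            i: (color[i], tuple(sorted(color[j] for j in neighbors[i])))
            for i in color
        }
        palette = {v: i for i, v in enumerate(sorted(set(sig.values())))}
        new_color = {i: palette[sig[i]] for i in sig}
        rounds += 1
        if len(set(new_color.values())) == len(set(color.values())):
            color = new_color
            break
        color = new_color
    groups: dict[int, set[int]] = {}
    for i, c in color.items():
        groups.setdefault(c, set()).add(i)
    classes = tuple(
        frozenset(s) for s in sorted(groups.values(), key=lambda s: min(s))
    )
    return OrbitPartition(classes=classes, refinement_rounds=rounds)
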