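"""Deterministic hydrogen ranking and labeling.

Hydrogens attached to one heavy center are distinguished by imposing a
temporary chiral perturbation: each hydrogen in turn receives a marker
isotope (deuterium, or the next unused mass number), and the standard InChI
of the resulting isotopomer — stereo layers included — is that hydrogen's
*signature*.  Chemically distinguishable hydrogens (diastereotopic pairs,
enantiotopic pairs made R/S by the substitution) produce distinct variant
strings and are ranked by lexicographic comparison of those strings, which
is independent of the input atom order.

Hydrogens whose signatures tie are symmetry-equivalent in the identifier's
eyes.  They are resolved by an iterative symmetry-breaking procedure: a
permanent marker is fixed on one member, the remaining members are re-signed
against the symmetry-broken molecule, and the process recurses until every
hydrogen holds a unique rank.  Members of a tied class are chemically
interchangeable, so the whole class is flagged as such; the input-index
tie-break used for anchors is confined to those provably equivalent atoms.

Primary amides get a geometric rule instead: the standard identifier treats
both amide hydrogens as one exchangeable pool (their isotopomer InChIs are
identical), yet they are rigid and NMR-distinct, so the hydrogen syn to the
carbonyl oxygen (smaller absolute H–N–C=O dihedral) ranks before the anti
one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .heavy_labeling import LabelAssignment
from .inchi_engine import InChIEngine, InChIRecord, default_engine
from .molgraph import MolGraph, write_molblock

__all__ = [
    "HydrogenRanking",
    "perturb_and_sign",
    "break_symmetry",
    "amide_rank",
    "assign_hydrogen_labels",
    "is_primary_amide_nitrogen",
    "engine_call_bound",
]

logger = logging.getLogger(__name__)

DIHEDRAL_TOL = 1e-6  # rad; fixture coordinates are exact to write precision


@dataclass
class HydrogenRanking:
    """Signatures, equivalence classes and ranks of one center's hydrogens."""

    center: int
    hydrogens: list[int]
    variant_signature: dict[int, str] = field(default_factory=dict)
    classes: list[list[int]] = field(default_factory=list)
    class_kind: dict[int, str] = field(default_factory=dict)  # class idx -> kind
    rank: dict[int, int] = field(default_factory=dict)

    def resolved(self) -> bool:
        return sorted(self.rank.values()) == list(
            range(1, len(self.hydrogens) + 1)
        )

    def interchangeable_classes(self) -> list[list[int]]:
        return [
            cls
            for i, cls in enumerate(self.classes)
            if len(cls) > 1 and self.class_kind.get(i) == "homotopic"
        ]


def _marker_masses(mol: MolGraph) -> list[int]:
    """Usable H marker masses, avoiding isotope labels already in the input.

    The reference engine accepts only deuterium and tritium as hydrogen
    isotopes, so at most two marker masses exist; classes that stay tied
    once the markers are exhausted are genuinely homotopic and fall back to
    input-index order.
    """
    used = {
        a.isotope_mass for a in mol.atoms if a.element == "H" and a.isotope_mass
    }
    if used:
        logger.warning(
            "input carries isotopically labeled hydrogens %s; falling back "
            "to the remaining marker masses", sorted(used)
        )
    return [m for m in (2, 3) if m not in used]


def _sign(mol: MolGraph, hydrogens: list[int], mass: int,
          engine: InChIEngine) -> dict[int, str]:
    sigs: dict[int, str] = {}
    for h in hydrogens:
        variant = mol.with_isotope(h, mass)
        sigs[h], _ = engine.run(write_molblock(variant))
    return sigs


def _group_by_signature(sigs: dict[int, str]) -> list[list[int]]:
    """Classes ordered by lexicographic signature; members by input index."""
    groups: dict[str, list[int]] = {}
    for h in sorted(sigs):
        groups.setdefault(sigs[h], []).append(h)
    return [groups[s] for s in sorted(groups)]


def perturb_and_sign(
    mol: MolGraph, center: int, engine: InChIEngine | None = None
) -> HydrogenRanking:
    """Signature every hydrogen of ``center`` with a marker isotope.

    Requires >= 2 attached hydrogens (a lone hydrogen needs no
    disambiguation).  Equal signatures define the equivalence classes;
    unequal signatures order the classes deterministically.
    """
    engine = engine or default_engine
    hydrogens = mol.hydrogen_neighbors(center)
    if len(hydrogens) < 2:
        raise ValueError(
            f"center {center} has {len(hydrogens)} hydrogens; nothing to rank"
        )
    mass = _marker_masses(mol)[0]
    ranking = HydrogenRanking(center=center, hydrogens=hydrogens)
    ranking.variant_signature = _sign(mol, hydrogens, mass, engine)
    ranking.classes = _group_by_signature(ranking.variant_signature)
    for i, cls in enumerate(ranking.classes):
        ranking.class_kind[i] = "distinct" if len(cls) == 1 else "homotopic"
    return ranking


def _resolve_tied(
    mol: MolGraph,
    members: list[int],
    masses: list[int],
    engine: InChIEngine,
) -> list[int]:
    """Order a signature-tied hydrogen class by iterative symmetry breaking.

    Fixes a permanent marker on the smallest-index member, re-signs the rest
    against the broken molecule with the next marker mass, and recurses into
    any still-tied subclass.  Terminates after at most ``len(members)``
    rounds because each round removes one anchor.
    """
    if len(members) <= 1:
        return list(members)
    if len(masses) < 2:
        # Marker masses exhausted: the members are homotopic beyond the
        # engine's isotope vocabulary; sequential order by input index.
        return sorted(members)
    anchor = min(members)
    rest = [h for h in members if h != anchor]
    broken = mol.with_isotope(anchor, masses[0])
    if len(rest) == 1:
        return [anchor] + rest
    sigs = _sign(broken, rest, masses[1], engine)
    order: list[int] = [anchor]
    for cls in _group_by_signature(sigs):
        order.extend(_resolve_tied(broken, cls, masses[1:], engine))
    return order


def break_symmetry(
    mol: MolGraph,
    pending: list[HydrogenRanking],
    engine: InChIEngine | None = None,
) -> list[HydrogenRanking]:
    """Resolve tied signature classes until every hydrogen holds a unique rank.

    Classes that required artificial markers to separate are genuinely
    interchangeable and stay flagged ``homotopic``; the ranks inside them
    are deterministic but rest on the input-index anchor choice.
    """
    engine = engine or default_engine
    masses = _marker_masses(mol)
    for ranking in pending:
        guard = len(ranking.hydrogens) + 1
        next_rank = 1
        for i, cls in enumerate(ranking.classes):
            if len(cls) == 1:
                ranking.rank[cls[0]] = next_rank
                next_rank += 1
                continue
            order = _resolve_tied(mol, cls, masses, engine)
            if len(order) != len(cls) or len(set(order)) != len(cls):
                raise RuntimeError(
                    f"symmetry breaking failed to resolve class {cls} "
                    f"at center {ranking.center} within {guard} rounds"
                )
            for h in order:
                ranking.rank[h] = next_rank
                next_rank += 1
        if not ranking.resolved():
            raise RuntimeError(
                f"center {ranking.center}: ranks incomplete after symmetry breaking"
            )
    return pending


# ---------------------------------------------------------------------------
# Primary amides


def is_primary_amide_nitrogen(mol: MolGraph, index: int) -> bool:
    """N bonded to exactly two H and (single bond) to a carbonyl carbon."""
    atom = mol.atom(index)
    if atom.element != "N":
        return False
    hs = mol.hydrogen_neighbors(index)
    if len(hs) != 2:
        return False
    for j in mol.neighbors(index):
        nb = mol.atom(j)
        if nb.element != "C":
            continue
        bond = mol.bond_between(index, j)
        if bond is None or bond.order != 1:
            continue
        for k in mol.neighbors(j):
            ob = mol.bond_between(j, k)
            if mol.atom(k).element == "O" and ob is not None and ob.order == 2:
                return True
    return False


def _dihedral(p0, p1, p2, p3) -> float:
    def sub(u, v):
        return (u[0] - v[0], u[1] - v[1], u[2] - v[2])

    def cross(u, v):
        return (
            u[1] * v[2] - u[2] * v[1],
            u[2] * v[0] - u[0] * v[2],
            u[0] * v[1] - u[1] * v[0],
        )

    def dot(u, v):
        return u[0] * v[0] + u[1] * v[1] + u[2] * v[2]

    b0, b1, b2 = sub(p1, p0), sub(p2, p1), sub(p3, p2)
    n1, n2 = cross(b0, b1), cross(b1, b2)
    m1 = cross(n1, b1)
    norm = math.sqrt(dot(b1, b1))
    x = dot(n1, n2)
    y = dot(m1, n2) / norm if norm else 0.0
    return math.atan2(y, x)


def amide_rank(mol: MolGraph, center: int) -> HydrogenRanking:
    """Rank a primary amide's NH2 geometrically: syn to the carbonyl first.

    The syn/anti call uses the absolute H–N–C=O dihedral, which is invariant
    under mirror reflection, so enantiomeric depositions agree.  A degenerate
    geometry (equal dihedrals within tolerance) falls back to homotopic
    handling with a log message.
    """
    if not is_primary_amide_nitrogen(mol, center):
        raise ValueError(f"atom {center} is not a primary-amide nitrogen")
    hydrogens = mol.hydrogen_neighbors(center)
    carbon = next(
        j
        for j in mol.neighbors(center)
        if mol.atom(j).element == "C"
        and any(
            mol.atom(k).element == "O"
            and (b := mol.bond_between(j, k)) is not None
            and b.order == 2
            for k in mol.neighbors(j)
        )
    )
    oxygen = next(
        k
        for k in mol.neighbors(carbon)
        if mol.atom(k).element == "O"
        and (b := mol.bond_between(carbon, k)) is not None
        and b.order == 2
    )
    ranking = HydrogenRanking(center=center, hydrogens=hydrogens)
    angles = {
        h: abs(
            _dihedral(
                mol.atom(h).coords,
                mol.atom(center).coords,
                mol.atom(carbon).coords,
                mol.atom(oxygen).coords,
            )
        )
        for h in hydrogens
    }
    a, b = hydrogens
    if abs(angles[a] - angles[b]) < DIHEDRAL_TOL:
        logger.warning(
            "amide at N%d has degenerate geometry; hydrogens treated as homotopic",
            center,
        )
        ranking.classes = [sorted(hydrogens)]
        ranking.class_kind[0] = "homotopic"
        for r, h in enumerate(sorted(hydrogens), start=1):
            ranking.rank[h] = r
        return ranking
    syn_first = sorted(hydrogens, key=lambda h: angles[h])
    ranking.classes = [[h] for h in syn_first]
    ranking.class_kind = {0: "amide_geometric", 1: "amide_geometric"}
    for r, h in enumerate(syn_first, start=1):
        ranking.rank[h] = r
    return ranking


# ---------------------------------------------------------------------------
# Final hydrogen labels


def assign_hydrogen_labels(
    mol: MolGraph,
    rec: InChIRecord,
    partial: LabelAssignment,
    rankings: list[HydrogenRanking],
) -> LabelAssignment:
    """Complete the assignment: hydrogens labeled ``H<m>`` per component.

    ``m`` counts on from the component's heavy-atom total; the sequence is
    ordered by (attached heavy atom's canonical number, rank within the
    center).  Interchangeable sets are populated from tied hydrogen classes
    and from InChI's constitutional equivalence classes of heavy atoms
    (AuxInfo /E:), each bundled with its attached hydrogens — those labels
    can migrate within their class under input renumbering, all others are
    pinned.
    """
    by_center = {r.center: r for r in rankings}
    for r in rankings:
        if not r.resolved():
            raise RuntimeError(f"center {r.center} has unranked hydrogens")
    h_label: dict[int, str] = {}
    for k, cmap in enumerate(rec.canonical_map):
        prefix = f"c{k + 1}." if rec.n_components > 1 else ""
        n_heavy = len(cmap)
        pos = n_heavy
        for canon in sorted(cmap):
            center = cmap[canon]
            hs = mol.hydrogen_neighbors(center)
            if not hs:
                continue
            if len(hs) == 1:
                ordered = hs
            else:
                ranking = by_center.get(center)
                if ranking is None:
                    raise RuntimeError(
                        f"multi-hydrogen center {center} has no ranking"
                    )
                ordered = sorted(hs, key=lambda h: ranking.rank[h])
            for h in ordered:
                pos += 1
                partial.add(h, f"{prefix}H{pos}", component=k + 1)
                h_label[h] = f"{prefix}H{pos}"
    unlabeled = [a.index for a in mol.atoms if a.index not in partial.forward]
    if unlabeled:
        raise RuntimeError(f"atoms left unlabeled: {unlabeled}")

    new_sets: list[set[str]] = []
    for r in rankings:
        for cls in r.interchangeable_classes():
            new_sets.append({h_label[h] for h in cls})
    # Heavy-atom equivalence classes (constitutional, from AuxInfo /E:),
    # bundled with each member's hydrogens.
    for k, cmap in enumerate(rec.canonical_map):
        for eq_class in rec.equivalence[k] if k < len(rec.equivalence) else []:
            if len(eq_class) < 2:
                continue
            bundle: set[str] = set()
            for canon in eq_class:
                center = cmap[canon]
                bundle.add(partial.forward[center])
                for h in mol.hydrogen_neighbors(center):
                    bundle.add(partial.forward[h])
            new_sets.append(bundle)
    partial.merge_interchangeable(new_sets)
    return partial


def engine_call_bound(mol: MolGraph) -> int:
    """Documented upper bound on engine invocations for one molecule.

    One base call, plus for every center with n >= 2 hydrogens at most
    n + n(n+1)/2 calls (initial signatures plus recursive re-signing during
    symmetry breaking, each round re-signing one fewer member).
    """
    bound = 1
    for i in mol.heavy_indices():
        n = len(mol.hydrogen_neighbors(i))
        if n >= 2:
            bound += n + n * (n + 1) // 2
    return bound
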