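"""Structure-file data model and I/O.

The molecular graph used throughout this package is a faithful image of an
MDL MOL V2000 atom/bond block: atoms keep their 1-based file indices, every
hydrogen is an explicit atom, and nothing is normalized on input.  Unique
atom labeling is only reproducible when the structure file is complete, so
the parser never invents hydrogens and rejects aromatic (type-4) bonds with
instructions to supply a Kekulé structure.

Multi-record SDF input is supported; each record becomes one
:class:`MolGraph` and SDF data fields are captured in ``properties``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Atom",
    "Bond",
    "MolGraph",
    "MolfileError",
    "parse_molfile",
    "parse_smiles",
    "write_molblock",
    "write_labeled_sdf",
    "hill_formula",
    "connected_components",
    "permute_atoms",
    "mirror",
    "union",
]

# Wedge codes of the MOL bond block (column 4).
_WEDGE_FROM_CODE = {0: "none", 1: "up", 6: "down"}
_CODE_FROM_WEDGE = {v: k for k, v in _WEDGE_FROM_CODE.items()}

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Fr", "Ra", "Ac", "Th", "Pa", "U",
}


class MolfileError(ValueError):
    """Malformed or unsupported structure-file content."""


@dataclass(frozen=True)
class Atom:
    """One atom of the MOL atom block, 1-based ``index`` as in the file."""

    index: int
    element: str
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    formal_charge: int = 0
    isotope_mass: int | None = None
    input_label: str | None = None

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def __post_init__(self) -> None:
        if self.element not in _ELEMENTS:
            raise MolfileError(f"unknown element symbol {self.element!r}")


@dataclass(frozen=True)
class Bond:
    """Connection-table entry; ``order`` in {1,2,3}, ``wedge`` for 2D stereo."""

    a: int
    b: int
    order: int = 1
    wedge: str = "none"

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise MolfileError(f"bond connects atom {self.a} to itself")
        if self.order not in (1, 2, 3):
            raise MolfileError(
                f"bond order {self.order} unsupported; aromatic (type-4) bonds "
                "must be supplied as an alternating Kekulé structure"
            )
        if self.wedge not in _CODE_FROM_WEDGE:
            raise MolfileError(f"unknown wedge flag {self.wedge!r}")

    @property
    def key(self) -> frozenset[int]:
        return frozenset((self.a, self.b))


@dataclass
class MolGraph:
    """A parsed structure record: explicit atoms, bonds, title, data fields."""

    atoms: list[Atom]
    bonds: list[Bond]
    title: str = ""
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = list(range(1, len(self.atoms) + 1))
        if [a.index for a in self.atoms] != expected:
            raise MolfileError("atom indices must be contiguous and 1-based")
        index_set = set(expected)
        seen: set[frozenset[int]] = set()
        for b in self.bonds:
            if b.a not in index_set or b.b not in index_set:
                raise MolfileError(
                    f"bond {b.a}-{b.b} references a nonexistent atom"
                )
            if b.key in seen:
                raise MolfileError(f"duplicate bond {b.a}-{b.b}")
            seen.add(b.key)

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, index: int) -> Atom:
        return self.atoms[index - 1]

    @property
    def dimensionality(self) -> str:
        return "3D" if any(abs(a.z) > 1e-9 for a in self.atoms) else "2D"

    def neighbors(self, index: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a == index:
                out.append(b.b)
            elif b.b == index:
                out.append(b.a)
        return sorted(out)

    def bond_between(self, i: int, j: int) -> Bond | None:
        key = frozenset((i, j))
        for b in self.bonds:
            if b.key == key:
                return b
        return None

    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]

    def hydrogen_neighbors(self, index: int) -> list[int]:
        return [j for j in self.neighbors(index) if self.atom(j).element == "H"]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element)
        for b in self.bonds:
            g.add_edge(b.a, b.b, order=b.order)
        return g

    def copy(self) -> "MolGraph":
        return MolGraph(
            atoms=list(self.atoms),
            bonds=list(self.bonds),
            title=self.title,
            properties=dict(self.properties),
        )

    def with_isotope(self, index: int, mass: int | None) -> "MolGraph":
        """Return a copy in which atom ``index`` carries ``mass``."""
        out = self.copy()
        out.atoms[index - 1] = replace(out.atoms[index - 1], isotope_mass=mass)
        return out

    def subgraph(self, indices: Iterable[int]) -> tuple["MolGraph", dict[int, int]]:
        """Extract the induced subgraph.

        Returns the new graph (atoms renumbered contiguously, file order
        preserved) and the old-index -> new-index map.
        """
        keep = sorted(set(indices))
        old2new = {old: new for new, old in enumerate(keep, start=1)}
        atoms = [
            replace(self.atom(old), index=old2new[old]) for old in keep
        ]
        bonds = [
            replace(b, a=old2new[b.a], b=old2new[b.b])
            for b in self.bonds
            if b.a in old2new and b.b in old2new
        ]
        return MolGraph(atoms, bonds, title=self.title), old2new


# ---------------------------------------------------------------------------
# MOL / SDF reading


def _split_records(text: str) -> list[str]:
    records = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append("\n".join(current))
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        records.append("\n".join(current))
    return records


def _parse_record(text: str) -> MolGraph:
    lines = text.split("\n")
    if len(lines) < 4:
        raise MolfileError("record too short to contain a molblock header")
    title = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileError("V3000 molblocks are not supported; supply V2000")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise MolfileError(f"malformed counts line: {counts!r}") from exc
    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileError("truncated molblock (atom/bond block shorter than counts)")

    atoms: list[Atom] = []
    legacy_mass: dict[int, int] = {}
    for i in range(n_atoms):
        line = lines[4 + i]
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
            symbol = line[31:34].strip()
        except (ValueError, IndexError) as exc:
            raise MolfileError(f"malformed atom line: {line!r}") from exc
        dd = line[34:36].strip()
        if dd and dd not in ("0", "00"):
            legacy_mass[i + 1] = int(dd)
        atoms.append(Atom(index=i + 1, element=symbol, x=x, y=y, z=z))

    bonds: list[Bond] = []
    for i in range(n_bonds):
        line = lines[4 + n_atoms + i]
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            order = int(line[6:9])
            stereo = int(line[9:12]) if line[9:12].strip() else 0
        except (ValueError, IndexError) as exc:
            raise MolfileError(f"malformed bond line: {line!r}") from exc
        if order == 4:
            raise MolfileError(
                "aromatic (type-4) bond encountered; supply a Kekulé structure "
                "with alternating single/double bonds"
            )
        wedge = _WEDGE_FROM_CODE.get(stereo, "none")
        bonds.append(Bond(a=a, b=b, order=order, wedge=wedge))

    charges: dict[int, int] = {}
    isotopes: dict[int, int] = {}
    aliases: dict[int, str] = {}
    properties: dict[str, str] = {}
    pos = 4 + n_atoms + n_bonds
    while pos < len(lines):
        line = lines[pos]
        if line.startswith("M  END"):
            pos += 1
            break
        if line.startswith("M  CHG"):
            fieldsv = line.split()[3:]
            for at, ch in zip(fieldsv[0::2], fieldsv[1::2]):
                charges[int(at)] = int(ch)
        elif line.startswith("M  ISO"):
            fieldsv = line.split()[3:]
            for at, mass in zip(fieldsv[0::2], fieldsv[1::2]):
                isotopes[int(at)] = int(mass)
        elif line.startswith("A  "):
            at = int(line[3:].strip())
            pos += 1
            aliases[at] = lines[pos].strip() if pos < len(lines) else ""
        pos += 1

    # SDF data fields
    name = None
    buf: list[str] = []
    for line in lines[pos:]:
        m = re.match(r">\s+<(.+?)>", line)
        if m:
            if name is not None:
                properties[name] = "\n".join(buf).strip("\n")
            name = m.group(1)
            buf = []
        elif name is not None:
            buf.append(line)
    if name is not None:
        properties[name] = "\n".join(buf).strip("\n")

    if not isotopes and legacy_mass:
        # legacy mass-diff column: convert via most common isotope masses
        from rdkit import Chem

        table = Chem.GetPeriodicTable()
        for at, dd in legacy_mass.items():
            base = int(round(table.GetMostCommonIsotopeMass(atoms[at - 1].element)))
            isotopes[at] = base + dd

    final_atoms = [
        replace(
            a,
            formal_charge=charges.get(a.index, 0),
            isotope_mass=isotopes.get(a.index),
            input_label=aliases.get(a.index),
        )
        for a in atoms
    ]
    mol = MolGraph(final_atoms, bonds, title=title, properties=properties)
    if "INPUT_LABELS" in properties:
        mol = apply_input_labels(mol, properties["INPUT_LABELS"])
    return mol


def apply_input_labels(mol: MolGraph, text: str) -> MolGraph:
    """Attach free-text input labels given as "index label" lines."""
    out = mol.copy()
    for line in text.splitlines():
        parts = line.split(None, 1)
        if len(parts) != 2:
            continue
        idx = int(parts[0])
        out.atoms[idx - 1] = replace(out.atoms[idx - 1], input_label=parts[1])
    return out


def parse_molfile(text: str) -> list[MolGraph]:
    """Parse MOL V2000 / SDF content into one :class:`MolGraph` per record."""
    return [_parse_record(rec) for rec in _split_records(text)]


def parse_molfile_lenient(text: str) -> list["MolGraph | MolfileError"]:
    """Per-record parse that reports failures in place of raising.

    Batch processing of multi-record SDF input must not let one corrupt
    record abort the remaining ones; each list position holds either the
    parsed graph or the record's :class:`MolfileError`.
    """
    out: list[MolGraph | MolfileError] = []
    for rec in _split_records(text):
        try:
            out.append(_parse_record(rec))
        except MolfileError as exc:
            out.append(exc)
    return out


# ---------------------------------------------------------------------------
# MOL / SDF writing


def write_molblock(mol: MolGraph) -> str:
    """Serialize to a V2000 molblock (coordinates at 4 decimals)."""
    lines = [mol.title, "  inchilabel", ""]
    lines.append(
        "%3d%3d  0  0  0  0  0  0  0  0999 V2000" % (len(mol.atoms), len(mol.bonds))
    )
    for a in mol.atoms:
        lines.append(
            "%10.4f%10.4f%10.4f %-3s 0  0  0  0  0  0  0  0  0  0  0  0"
            % (a.x, a.y, a.z, a.element)
        )
    for b in mol.bonds:
        lines.append("%3d%3d%3d%3d" % (b.a, b.b, b.order, _CODE_FROM_WEDGE[b.wedge]))
    charges = [(a.index, a.formal_charge) for a in mol.atoms if a.formal_charge]
    for start in range(0, len(charges), 8):
        chunk = charges[start : start + 8]
        lines.append(
            "M  CHG%3d" % len(chunk)
            + "".join("%4d%4d" % pair for pair in chunk)
        )
    isotopes = [(a.index, a.isotope_mass) for a in mol.atoms if a.isotope_mass]
    for start in range(0, len(isotopes), 8):
        chunk = isotopes[start : start + 8]
        lines.append(
            "M  ISO%3d" % len(chunk)
            + "".join("%4d%4d" % pair for pair in chunk)
        )
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def write_sdf_record(mol: MolGraph, properties: Mapping[str, str] | None = None) -> str:
    block = write_molblock(mol)
    props = dict(mol.properties)
    if properties:
        props.update(properties)
    parts = [block.rstrip("\n")]
    for key, value in props.items():
        parts.append(f">  <{key}>")
        parts.append(value)
        parts.append("")
    parts.append("$$$$")
    return "\n".join(parts) + "\n"


def write_labeled_sdf(mol: MolGraph, labels) -> str:
    """Write an SDF record with atoms reordered into unique-label order.

    The unique labels are emitted in a ``UNIQUE_LABELS`` data field (one
    "index label" pair per line, indices referring to the *reordered* atom
    block) and the input -> output correspondence in an ``INPUT_MAP`` field
    (one "input_index unique_label" pair per line).
    """
    missing = [a.index for a in mol.atoms if a.index not in labels.forward]
    if missing:
        raise ValueError(f"label assignment does not cover atoms {missing}")
    order = sorted(mol.atoms, key=lambda a: labels.sort_key(labels.forward[a.index]))
    perm = {a.index: new for new, a in enumerate(order, start=1)}
    reordered = permute_atoms(mol, perm)
    label_lines = "\n".join(
        f"{perm[a.index]} {labels.forward[a.index]}" for a in order
    )
    map_lines = "\n".join(
        f"{a.index} {labels.forward[a.index]}" for a in mol.atoms
    )
    return write_sdf_record(
        reordered, {"UNIQUE_LABELS": label_lines, "INPUT_MAP": map_lines}
    )


# ---------------------------------------------------------------------------
# SMILES front end (audit utilities)


def parse_smiles(s: str) -> MolGraph:
    """Parse a SMILES string into a MolGraph with explicit hydrogens.

    Tetrahedral stereo marks are preserved through wedge bonds on a 2D
    depiction layout; the record is marked 2D and intended for audit use.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.MolFromSmiles(s)
    if rd is None:
        raise MolfileError(f"unparsable SMILES: {s!r}")
    rd = Chem.AddHs(rd)
    AllChem.Compute2DCoords(rd)
    block = Chem.MolToMolBlock(rd, kekulize=True)
    mol = parse_molfile(block)[0]
    return MolGraph(mol.atoms, mol.bonds, title=s)


# ---------------------------------------------------------------------------
# Derived quantities and fixture transforms


def _component_formula(mol: MolGraph, indices: Iterable[int]) -> str:
    counts: dict[str, int] = {}
    for i in indices:
        el = mol.atom(i).element
        counts[el] = counts.get(el, 0) + 1
    return format_hill(counts)


def format_hill(counts: Mapping[str, int]) -> str:
    """Format an element-count map in Hill order (C, H, then alphabetical)."""
    parts: list[str] = []
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else []) + sorted(
            k for k in counts if k not in ("C", "H")
        )
    else:
        order = sorted(counts)
    for el in order:
        n = counts[el]
        parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def hill_formula(mol: MolGraph) -> str:
    """Hill formula; disconnected components joined with '.' in sorted order."""
    comps = connected_components(mol)
    formulas = sorted(_component_formula(mol, comp) for comp in comps)
    return ".".join(formulas)


def connected_components(mol: MolGraph) -> list[list[int]]:
    """Partition of atom indices into connected components.

    Components are ordered by their smallest contained atom index; atoms
    inside a component are sorted ascending.
    """
    g = mol.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def permute_atoms(mol: MolGraph, perm: Mapping[int, int] | Sequence[int]) -> MolGraph:
    """Reorder the atom block by a bijection old-index -> new-index.

    Coordinates, charges, isotopes and labels travel with their atoms; bonds
    are re-indexed.  SDF properties are dropped (they may reference the old
    numbering).
    """
    n = len(mol.atoms)
    if not isinstance(perm, Mapping):
        perm = {i + 1: p for i, p in enumerate(perm)}
    if sorted(perm) != list(range(1, n + 1)) or sorted(perm.values()) != list(
        range(1, n + 1)
    ):
        raise ValueError("perm is not a bijection on 1..n")
    atoms: list[Atom | None] = [None] * n
    for a in mol.atoms:
        atoms[perm[a.index] - 1] = replace(a, index=perm[a.index])
    bonds = [replace(b, a=perm[b.a], b=perm[b.b]) for b in mol.bonds]
    return MolGraph(list(atoms), bonds, title=mol.title)


def mirror(mol: MolGraph) -> MolGraph:
    """Reflect the structure: negate z for 3D input, flip wedges for 2D."""
    if mol.dimensionality == "3D":
        atoms = [replace(a, z=-a.z) for a in mol.atoms]
        return MolGraph(atoms, list(mol.bonds), title=mol.title)
    flip = {"up": "down", "down": "up", "none": "none"}
    if all(b.wedge == "none" for b in mol.bonds):
        raise MolfileError("cannot mirror a 2D structure without wedge bonds")
    bonds = [replace(b, wedge=flip[b.wedge]) for b in mol.bonds]
    return MolGraph(list(mol.atoms), bonds, title=mol.title)


def union(mols: Sequence[MolGraph], title: str = "") -> MolGraph:
    """Concatenate several molecules into one (disconnected) record."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    offset = 0
    for m in mols:
        for a in m.atoms:
            atoms.append(replace(a, index=a.index + offset))
        for b in m.bonds:
            bonds.append(replace(b, a=b.a + offset, b=b.b + offset))
        offset += len(m.atoms)
    return MolGraph(atoms, bonds, title=title)
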