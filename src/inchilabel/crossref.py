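"""Cross-database auditing: identifier validation, matching, concordances.

Databases deposit InChI strings alongside structure files, and the two
drift apart: legacy non-standard prefixes, dropped stereo layers, wrong
protonation.  This module recomputes the identifier from the structure and
classifies any discrepancy layer-by-layer; builds cross references between
entry tables by exact standard-InChI identity; validates claimed links; and
constructs atom-label concordances between independently numbered structure
files of the same compound.

Entry tables are plain TSV with a header row ``entry_id  inchi
structure_file`` — a neutral interface in place of database-specific
archive scrapers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .inchi_engine import InChIEngine, InChIRecord, InChIError, compute_inchi, \
    default_engine, parse_layers
from .mixtures import process_record
from .molgraph import MolGraph, parse_molfile

__all__ = [
    "AuditRecord",
    "Concordance",
    "CLASSIFICATIONS",
    "classify_deposited",
    "match_entries",
    "validate_crossref",
    "atom_concordance",
    "load_entry_table",
    "audit_table",
    "concordance_table",
]

CLASSIFICATIONS = (
    "exact_match",
    "non_standard_string",
    "missing_stereo",
    "missing_protonation",
    "charge_mismatch",
    "formula_mismatch",
    "missing_deposited",
    "other_mismatch",
)

_STEREO_TAGS = ("t", "m", "s")


@dataclass
class AuditRecord:
    """One entry's deposited vs. recomputed identifier and the verdict."""

    source: str
    entry_id: str
    deposited_inchi: str
    computed_inchi: str
    classification: str
    detail: str = ""


@dataclass
class Concordance:
    """Atom-to-atom correspondence between two files of one compound."""

    entry_a: str
    entry_b: str
    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    complete: bool = False
    reason: str = ""


def _layer_diff(dep: dict[str, str], comp: dict[str, str]) -> str:
    tags = sorted(set(dep) | set(comp))
    out = []
    for tag in tags:
        d, c = dep.get(tag), comp.get(tag)
        if d != c:
            out.append(f"/{tag}: deposited={d!r} computed={c!r}")
    return "; ".join(out)


def classify_deposited(
    deposited: str,
    computed: InChIRecord | str,
    source: str = "",
    entry_id: str = "",
) -> AuditRecord:
    """Classify a deposited identifier against the recomputed one.

    The classification is total and follows a fixed precedence:
    missing_deposited, non_standard_string, formula_mismatch,
    charge_mismatch (/q), missing_protonation (/p), missing_stereo
    (deposited lacks /t, /m or /s layers the computed string carries while
    everything else agrees), other_mismatch; byte-for-byte equality — and
    only that — is exact_match.
    """
    comp_inchi = computed if isinstance(computed, str) else computed.inchi

    def record(cls: str, detail: str = "") -> AuditRecord:
        return AuditRecord(source, entry_id, deposited, comp_inchi, cls, detail)

    if deposited == comp_inchi:
        return record("exact_match")
    if not deposited or not deposited.strip():
        return record("missing_deposited", "no deposited identifier")
    try:
        dep_layers, _ = parse_layers(deposited.strip())
    except InChIError as exc:
        return record("non_standard_string", str(exc))
    comp_layers, _ = parse_layers(comp_inchi)
    diff = _layer_diff(dep_layers, comp_layers)
    if dep_layers["formula"] != comp_layers["formula"]:
        return record("formula_mismatch", diff)
    if dep_layers.get("q") != comp_layers.get("q"):
        return record("charge_mismatch", diff)
    if dep_layers.get("p") != comp_layers.get("p"):
        return record("missing_protonation", diff)
    dep_other = {k: v for k, v in dep_layers.items() if k not in _STEREO_TAGS}
    comp_other = {k: v for k, v in comp_layers.items() if k not in _STEREO_TAGS}
    if dep_other == comp_other:
        lacks = [
            tag
            for tag in _STEREO_TAGS
            if tag in comp_layers and tag not in dep_layers
        ]
        conflicting = [
            tag
            for tag in _STEREO_TAGS
            if tag in dep_layers and dep_layers.get(tag) != comp_layers.get(tag)
        ]
        if lacks and not conflicting:
            return record("missing_stereo", diff)
    return record("other_mismatch", diff)


def match_entries(
    a: list[tuple[str, InChIRecord | str]],
    b: list[tuple[str, InChIRecord | str]],
) -> list[tuple[str, str]]:
    """Cross references by byte-identical computed standard InChI.

    Many-to-many pairings are all reported; output is id-sorted and
    deterministic.  A duplicate id inside one list is an error.
    """

    def table(entries, side):
        ids = [e[0] for e in entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate id in list {side}: {sorted(dupes)}")
        return {
            eid: (rec if isinstance(rec, str) else rec.inchi)
            for eid, rec in entries
        }

    ta, tb = table(a, "a"), table(b, "b")
    by_inchi: dict[str, list[str]] = {}
    for eid, inchi in tb.items():
        by_inchi.setdefault(inchi, []).append(eid)
    pairs = [
        (ida, idb)
        for ida, inchi in ta.items()
        for idb in by_inchi.get(inchi, [])
    ]
    return sorted(pairs)


def validate_crossref(
    pairs: list[tuple[str, str]],
    a: list[tuple[str, InChIRecord | str]],
    b: list[tuple[str, InChIRecord | str]],
) -> list[dict]:
    """Verdict per claimed (id_a, id_b) link.

    ``valid`` iff the computed InChIs are identical; otherwise ``invalid``
    with the layer diff attached; a dangling id yields ``unresolvable``.
    """
    ta = {eid: (r if isinstance(r, str) else r.inchi) for eid, r in a}
    tb = {eid: (r if isinstance(r, str) else r.inchi) for eid, r in b}
    out = []
    for ida, idb in pairs:
        if ida not in ta or idb not in tb:
            out.append(
                {"id_a": ida, "id_b": idb, "verdict": "unresolvable", "detail": ""}
            )
            continue
        ia, ib = ta[ida], tb[idb]
        if ia == ib:
            out.append({"id_a": ida, "id_b": idb, "verdict": "valid", "detail": ""})
        else:
            la, _ = parse_layers(ia)
            lb, _ = parse_layers(ib)
            out.append(
                {
                    "id_a": ida,
                    "id_b": idb,
                    "verdict": "invalid",
                    "detail": _layer_diff(lb, la),
                }
            )
    return out


def atom_concordance(
    mol_a: MolGraph,
    mol_b: MolGraph,
    entry_a: str = "a",
    entry_b: str = "b",
    engine: InChIEngine | None = None,
) -> Concordance:
    """Atom-label concordance between two structure files.

    Both structures are labeled with the full pipeline; when their standard
    InChIs agree the unified labels join the two numbering schemes into a
    bijection (input label, or index when unlabeled, on either side).  A
    differing identifier yields an incomplete concordance with the
    layer-level reason — e.g. a stereo mismatch for an enantiomer pair.
    """
    engine = engine or default_engine
    ra = process_record(mol_a, engine)
    rb = process_record(mol_b, engine)
    conc = Concordance(entry_a=entry_a, entry_b=entry_b)
    if ra.record.inchi != rb.record.inchi:
        la, _ = parse_layers(ra.record.inchi)
        lb, _ = parse_layers(rb.record.inchi)
        only_stereo = all(
            la.get(t) == lb.get(t)
            for t in set(la) | set(lb)
            if t not in _STEREO_TAGS
        )
        kind = "stereo mismatch" if only_stereo else "identifier mismatch"
        conc.reason = f"{kind}: {_layer_diff(lb, la)}"
        return conc

    def input_name(mol: MolGraph, index: int) -> str:
        label = mol.atom(index).input_label
        return label if label else str(index)

    for label in sorted(ra.labels.inverse, key=ra.labels.sort_key):
        ia = ra.labels.inverse[label]
        ib = rb.labels.inverse[label]
        conc.pairs.append((input_name(mol_a, ia), input_name(mol_b, ib), label))
    conc.complete = len(conc.pairs) == len(mol_a.atoms) == len(mol_b.atoms)
    return conc


# ---------------------------------------------------------------------------
# TSV entry tables

_REQUIRED_COLUMNS = ["entry_id", "inchi", "structure_file"]


def load_entry_table(path: str) -> pd.DataFrame:
    """Read a TSV entry table, validating the header schema."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"entry table {path} lacks required column(s) {missing}; "
            f"found {list(table.columns)}"
        )
    return table


def audit_table(
    path: str, source: str = "", engine: InChIEngine | None = None
) -> list[AuditRecord]:
    """Audit every entry of a TSV table against its structure file.

    Structure paths resolve relative to the table's directory.  A missing
    or unreadable structure file classifies the row as ``missing_deposited``
    when no identifier was given either, else ``other_mismatch`` with the
    error recorded; remaining rows are still processed.
    """
    engine = engine or default_engine
    table = load_entry_table(path)
    base = os.path.dirname(os.path.abspath(path))
    out: list[AuditRecord] = []
    for row in table.itertuples(index=False):
        deposited = row.inchi.strip()
        spath = row.structure_file
        if not os.path.isabs(spath):
            spath = os.path.join(base, spath)
        try:
            with open(spath, encoding="utf-8") as fh:
                mol = parse_molfile(fh.read())[0]
            computed = compute_inchi(mol, engine)
        except (OSError, IndexError, ValueError, InChIError) as exc:
            out.append(
                AuditRecord(
                    source=source,
                    entry_id=row.entry_id,
                    deposited_inchi=deposited,
                    computed_inchi="",
                    classification="missing_deposited"
                    if not deposited
                    else "other_mismatch",
                    detail=f"structure unavailable: {exc}",
                )
            )
            continue
        out.append(
            classify_deposited(deposited, computed, source=source,
                               entry_id=row.entry_id)
        )
    return out


def audit_frame(records: list[AuditRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "entry_id": r.entry_id,
                "classification": r.classification,
                "deposited_inchi": r.deposited_inchi,
                "computed_inchi": r.computed_inchi,
                "detail": r.detail,
            }
            for r in records
        ]
    )


def concordance_table(conc: Concordance) -> pd.DataFrame:
    return pd.DataFrame(
        conc.pairs, columns=[conc.entry_a, conc.entry_b, "unified_label"]
    )
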