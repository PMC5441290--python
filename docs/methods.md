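# Methods

## Scope and model

`inchilabel` implements a deterministic protocol that turns a complete
structure file into (a) the standard InChI of the record and (b) a unique
label for every atom, with an audit layer for database cross-referencing.
The protocol's central assumption is that the structure file is the ground
truth: every hydrogen explicit, Kekulé bond orders, 2D wedges or 3D
coordinates carrying the stereochemistry. Nothing is normalized on input —
the parser rejects V3000 blocks and aromatic (type-4) bonds rather than
guessing, because silent kekulization or hydrogen completion would make the
derived identifiers depend on toolkit heuristics instead of on the
deposited bytes. An opt-in `--add-hydrogens` flag performs valence-based
completion with a logged warning for legacy files.

The reference InChI implementation (bundled with rdkit) is driven through
a narrow bytes-in/strings-out interface (`InChIEngine.run`): a V2000
molblock in, the standard identifier and AuxInfo out. The engine is never
asked for non-standard options, and every derived quantity is parsed from
the two strings, so the engine is swappable and its invocation count — the
protocol's hot path — is observable.

## Heavy atoms

InChI canonically numbers the heavy atoms of each component (carbons
first, then the remaining elements in formula order). The AuxInfo `/N:`
sub-layer maps canonical numbers back to input indices (`/F:` supersedes
it when a fixed-H renumbering is present). Before labels are written,
`verify_correspondence` re-derives the heavy-atom graph from the `/c`
layer grammar (chains, parenthesized branches, sibling commas, repeated
numbers as ring closures), relabels it through that map and requires exact
edge-set equality with the input graph plus element agreement with the
formula layer. Any mismatch is a hard error: it signals engine/parser
disagreement and must never be silently accepted. A heavy atom with
canonical number *n* and element *E* is labeled `E<n>`; the grammar is the
package's own choice (the mapping output makes renaming trivial), compact
and sortable.

## Hydrogens

A hydrogen's *signature* is the standard InChI of the isotopomer in which
only that hydrogen carries a marker isotope. The marker imposes a
temporary chiral center: enantiotopic hydrogens become R/S on substitution
(glycine's α-CH₂ gives `/i1D/t1-/m1/s1` vs `/m0`), diastereotopic pairs
differ in `/t`, and genuinely homotopic hydrogens give byte-identical
variants. Signatures are physical properties of the isotopomer molecule,
independent of the input atom order, so distinct signatures yield stable
ranks via lexicographic comparison of the variant strings. The ordering
convention between distinguishable hydrogens is this lexicographic rule;
any other convention (e.g. pro-R first) is a post-process on the emitted
map.

Tied classes are resolved by iterative symmetry breaking: fix a permanent
marker on one member (anchor = smallest input index; the choice is
confined to provably equivalent atoms), re-sign the remainder against the
broken molecule with the next marker mass, recurse. The engine accepts
only deuterium and tritium as hydrogen isotopes, so at most two marker
masses exist; a class still tied when markers are exhausted (methane's
last two hydrogens) is homotopic beyond the isotope vocabulary and falls
back to input-index order. Every class that required breaking is flagged
interchangeable.

Primary amides are the documented exception: InChI pools both NH₂
hydrogens into one exchangeable group (`/i/hD` for either isotopomer), yet
the amide bond is rigid and the two positions are NMR-distinct. For an N
with exactly two hydrogens single-bonded to a carbonyl carbon, the
hydrogen with the smaller absolute H–N–C=O dihedral (syn to the oxygen)
ranks first. The |dihedral| criterion is mirror-invariant, so enantiomeric
depositions agree; a degenerate geometry (difference < 1e-6 rad, matched
to coordinate write precision) falls back to homotopic handling with a
log message. Only primary amides are gated in; secondary amides carry at
most one N–H and need no rule.

Hydrogen labels continue the component's heavy count: `H<m>` with *m*
ordered by (center's canonical number, rank within center). Ethanol:
C1(H4–H6), C2(H7,H8), O3(H9).

## Interchangeable sets

Two kinds of labels can legitimately migrate under a renumbering of the
input file: hydrogens inside a tied signature class, and heavy atoms that
InChI itself cannot tell apart. For the latter the package uses the
AuxInfo `/E:` layer — the engine's own constitutional equivalence classes
of the normalized structure (mobile-hydrogen groups abstracted, bond
orders ignored). Each nontrivial class, bundled with its members'
hydrogens, becomes an interchangeable label set; transitively overlapping
sets are merged. This is deliberately conservative: atoms pinned by stereo
descriptors inside a constitutional class (two of myo-inositol's ring
carbons) may be flagged although their labels are in fact stable. The
guarantee that matters is one-sided and is asserted by the test suite:
labels outside every interchangeable set never move, and each
interchangeable set maps onto itself, over 50 random permutations of every
fixture.

The documented engine-invocation bound is `1 + Σ over multi-hydrogen
centers of (n_H + Σ over breaking rounds of remaining members)`, at most
`1 + Σ n_H(n_H+1)/2`; the tests assert it per fixture. Highly symmetric
molecules are cheap, not expensive: scyllo-inositol (one hydrogen per
center) needs exactly one engine call.

## Mixtures

A disconnected record's InChI concatenates per-component layers in
canonical component order, folding identical components with `k*`
multipliers; the AuxInfo `/N:` stays unfolded. Delamination expands the
formula split, matches each component's canonical map to a connected
component of the input graph, and labels each component with the ordinary
standalone pipeline — which makes "mixture labels equal standalone labels
after prefix stripping" true by construction and testable. Global labels
take a `c<ordinal>.` prefix (omitted for single-component records).
Identical components are chemically indistinguishable; their ordinal slots
are assigned by smallest original atom index and the blocks are flagged
interchangeable at block level, mirroring the homotopic-hydrogen policy.

## Cross-referencing

Deposited identifiers are classified against recomputed ones by a total,
layer-mechanical eight-way taxonomy with fixed precedence:
`missing_deposited`, `non_standard_string` (prefix ≠ `InChI=1S/`),
`formula_mismatch`, `charge_mismatch` (/q), `missing_protonation` (/p),
`missing_stereo` (deposited lacks /t, /m or /s layers the computed string
carries while all other layers agree; *conflicting* stereo is
`other_mismatch`), `other_mismatch`; byte equality alone is `exact_match`.
Cross references are created and validated by byte-exact standard-InChI
identity — no InChIKey hashing, no skeleton-level matching — because the
uniqueness argument rests on the standard string itself. Entry tables are
plain TSV (`entry_id, inchi, structure_file`); archive-format scrapers are
out of scope. Atom concordances label both files with the full pipeline
and join on the unified labels; interchangeable-set members are thereby
matched by rank, which is the only meaningful correspondence for
symmetry-equivalent atoms.

## Fixtures and what they do (not) show

The embedded set spans the protocol's branches: methane/water (homotopic
limits), ethanol (rotor + hydroxyl), glycine (enantiotopic CH₂, mobile
carboxyl H), acetamide (rigid amide NH₂), L-leucine (chiral center,
diastereotopic CH₂ and methyls), phosphonoacetic acid (two mobile-H
groups), toluene/benzene (ring symmetry), myo-/scyllo-inositol (meso
stereochemistry; scyllo's six CH positions are fully equivalent — their
CH-D isotopomers give one identical InChI), and an acetone/propen-2-ol
tautomer pair. Coordinates come from a seeded distance-geometry embedding
with MMFF minimization, frozen as text so expected identifiers refer to
exact bytes; fixture stereochemistry was pinned against the reference
engine (L-leucine reproduces the canonical `/t5-/m0/s1` string).

These are desk-scale, well-formed inputs. Passing tests demonstrate
determinism, permutation invariance and the correctness of the layer
mechanics; they do not exercise the long tail of real depositions
(charged species, radicals, polymers, malformed counts lines beyond the
cases tested) nor database-scale error statistics, which require archive
snapshots. Orbit refinement is exact on every shipped fixture (backed by
an exhaustive automorphism oracle for molecules ≤ 14 atoms) but is, in
general, an over-approximation of true orbits.

## Numerical and procedural choices

- Atom indices are 1-based everywhere, as in the MOL atom block.
- Marker masses: 2 then 3, shifted past any isotope labels already in the
  input (logged).
- Amide dihedral tolerance 1e-6 rad; coordinates are written at 4
  decimals.
- Stereo perception is the engine's: 3D from coordinates, 2D from wedges;
  `parse_smiles` goes through a 2D depiction with wedge bonds so
  tetrahedral marks survive (coordinates are depiction-only and flagged
  2D).
- All randomness lives in the fixture generators and is seeded; the
  labeling pipeline itself has none.
- Exit codes: 0 success, 1 total failure, 2 partial success on
  multi-record input.
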