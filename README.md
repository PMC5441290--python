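# inchilabel

Unique, reproducible molecule **and atom** identifiers for small organic
molecules, built entirely within the standard InChI convention.

## The problem

Databases of small molecules (NMR, metabolomics, ligand archives) key
atom-specific data — chemical shifts, coupling constants, reaction atom
maps — to their own local atom numbering. Two depositions of the same
compound routinely use incompatible numberings, and deposited InChI strings
drift from the structures they describe (dropped stereo layers, legacy
prefixes, wrong protonation). The standard InChI uniquely identifies the
*molecule* but canonically numbers only the heavy atoms and says nothing
about which hydrogen is which.

`inchilabel` closes that gap. From a complete (explicit-hydrogen) MOL
V2000/SDF structure file it derives:

- the standard InChI of the record,
- a unique label for every heavy atom, `E<n>` from its InChI canonical
  number `n` (ethanol: `C1 C2 O3`),
- a unique label for every hydrogen, `H<m>`, ranked deterministically even
  at chiral, prochiral, primary-amide and symmetric centers,
- per-component label blocks (`c2.O1`) for multi-molecule mixture records,
- and an audit layer that classifies deposited-InChI errors, validates and
  creates cross references, and builds atom-label concordances between
  independently numbered files of one compound.

## How hydrogens are ranked

Heavy atoms inherit InChI's canonical numbers after an explicit
verification that the `/c` connection layer, relabeled through the AuxInfo
`/N:` numbering, reproduces the input heavy-atom graph edge for edge.

Hydrogens on a shared center are distinguished by a *temporary chiral
perturbation*: each hydrogen in turn carries a marker isotope (deuterium,
then tritium), and the standard InChI of that isotopomer — stereo layers
included — is the hydrogen's signature. Diastereotopic and enantiotopic
hydrogens yield distinct variant strings (`/i3D/t3-,5+/m1` vs
`/i3D/t3-,5-` for the β-CH₂ of L-leucine) and are ordered by lexicographic
comparison of those strings, which no renumbering of the input can change.
Signature ties are broken iteratively by fixing a permanent marker and
re-signing the remainder; classes that needed artificial breaking are
genuinely homotopic and are flagged *interchangeable*. Primary-amide NH₂
hydrogens, which the identifier pools as exchangeable, are ranked
geometrically instead: syn to the carbonyl oxygen (smaller |H–N–C=O|
dihedral) before anti.

Symmetry-equivalent heavy atoms (InChI's AuxInfo `/E:` classes — the ring
carbons of scyllo-inositol, the two methyls of leucine) still receive
all-distinct labels; their label sets, bundled with attached hydrogens, are
flagged interchangeable so that downstream comparisons know exactly which
assignments are conventions rather than physics.

## Worked example

```python
import inchilabel as il
from inchilabel import fixtures

res = il.label_component(fixtures.graph("ethanol"))
print(res.record.inchi)
print(dict(sorted(res.labels.forward.items())))
print([sorted(s) for s in res.labels.interchangeable_sets])
```

prints

```
InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3
{1: 'C1', 2: 'C2', 3: 'O3', 4: 'H4', 5: 'H5', 6: 'H6', 7: 'H8', 8: 'H7', 9: 'H9'}
[['H4', 'H5', 'H6']]
```

Heavy atoms take their canonical numbers (the methyl carbon is canonical 1,
the hydroxyl oxygen 3). Hydrogens continue the count per center: the three
methyl hydrogens H4–H6 form one interchangeable (homotopic) set, the
prochiral CH₂ pair H7/H8 is pinned individually by its isotopomer
signatures, and the hydroxyl hydrogen is H9. The same molecule in any atom
order yields exactly these labels for the same physical atoms.

The command-line tool wraps the same pipeline:

```bash
inchilabel label ethanol.mol --out out/     # InChI + labeled SDF + atom map
inchilabel audit entries.tsv --out out/     # classify deposited identifiers
inchilabel concord a.mol b.mol --out out/   # atom-label concordance
inchilabel fixtures --out fixtures/ --seed 1
```

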