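"""Structure-file model: parsing, writing, formulas, fixture transforms."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from inchilabel import fixtures as fx
from inchilabel.molgraph import (
    MolfileError,
    MolGraph,
    apply_input_labels,
    connected_components,
    hill_formula,
    mirror,
    parse_molfile,
    parse_smiles,
    permute_atoms,
    union,
    write_labeled_sdf,
    write_molblock,
)


class TestParsing:
    def test_methane_counts(self, methane_molblock):
        (mol,) = parse_molfile(methane_molblock)
        assert len(mol.atoms) == 5
        assert len(mol.bonds) == 4
        assert [a.element for a in mol.atoms] == ["C", "H", "H", "H", "H"]

    def test_sdf_two_records_titles_preserved(self, methane_molblock):
        text = methane_molblock.rstrip() + "\n$$$$\n" + \
            fx.molblock("ethanol").rstrip() + "\n$$$$\n"
        mols = parse_molfile(text)
        assert [m.title for m in mols] == ["methane", "ethanol"]

    def test_leucine_counts_match_counts_line(self):
        # independent oracle: read the counts line of the raw fixture text
        counts = fx.molblock("l_leucine").split("\n")[3]
        n_atoms, n_bonds = int(counts[:3]), int(counts[3:6])
        mol = fx.graph("l_leucine")
        assert (len(mol.atoms), len(mol.bonds)) == (n_atoms, n_bonds) == (22, 21)

    def test_sdf_data_fields_captured(self, methane_molblock):
        text = methane_molblock.rstrip() + "\n>  <origin>\ntest suite\n\n$$$$\n"
        (mol,) = parse_molfile(text)
        assert mol.properties["origin"] == "test suite"

    @pytest.mark.parametrize(
        "mutation, message",
        [
            (lambda t: t.replace("V2000", "V3000"), "V3000"),
            (lambda t: t.replace("  1  2  1  0", "  1  9  1  0"), "nonexistent"),
            (lambda t: t.replace("  1  2  1  0", "  1  2  4  0"), "Kekul"),
            (lambda t: "\n".join(["x", "", "", "garbage counts"]), "counts"),
        ],
    )
    def test_malformed_input_rejected(self, methane_molblock, mutation, message):
        with pytest.raises(MolfileError, match=message):
            parse_molfile(mutation(methane_molblock))

    def test_input_labels_from_data_field(self, methane_molblock):
        text = methane_molblock.rstrip() + \
            "\n>  <INPUT_LABELS>\n1 CA\n2 HA1\n\n$$$$\n"
        (mol,) = parse_molfile(text)
        assert mol.atom(1).input_label == "CA"
        assert mol.atom(2).input_label == "HA1"
        assert mol.atom(3).input_label is None


class TestRoundTrip:
    def test_every_fixture_round_trips(self, fixture_name):
        mol = fx.graph(fixture_name)
        (back,) = parse_molfile(write_molblock(mol))
        assert [a.element for a in back.atoms] == [a.element for a in mol.atoms]
        assert {b.key for b in back.bonds} == {b.key for b in mol.bonds}
        assert [a.formal_charge for a in back.atoms] == \
            [a.formal_charge for a in mol.atoms]
        assert [a.isotope_mass for a in back.atoms] == \
            [a.isotope_mass for a in mol.atoms]

    def test_isotopes_and_charges_survive(self):
        mol = fx.graph("ethanol").with_isotope(4, 2)
        (back,) = parse_molfile(write_molblock(mol))
        assert back.atom(4).isotope_mass == 2

    def test_labeled_sdf_ethanol_has_nine_label_lines(self):
        from inchilabel.pipeline import label_component

        mol = fx.graph("ethanol")
        res = label_component(mol)
        text = write_labeled_sdf(mol, res.labels)
        (out,) = parse_molfile(text)
        label_lines = out.properties["UNIQUE_LABELS"].splitlines()
        assert len(label_lines) == 9
        # atoms reordered into label order: C1 first, hydroxyl H9 last
        assert label_lines[0].endswith("C1") and label_lines[-1].endswith("H9")
        # round trip under the stored input map: bond multiset preserved
        input_map = dict(
            line.split() for line in out.properties["INPUT_MAP"].splitlines()
        )
        new_index = {lbl: i + 1 for i, lbl in
                     enumerate(l.split()[1] for l in label_lines)}
        remap = {int(old): new_index[lbl] for old, lbl in input_map.items()}
        remapped = {frozenset((remap[b.a], remap[b.b])) for b in mol.bonds}
        assert remapped == {b.key for b in out.bonds}

    def test_labeled_sdf_requires_complete_labels(self):
        from inchilabel.heavy_labeling import LabelAssignment

        mol = fx.graph("methane")
        labels = LabelAssignment()
        labels.add(1, "C1")
        with pytest.raises(ValueError, match="cover"):
            write_labeled_sdf(mol, labels)


class TestSmiles:
    def test_cco_atom_census(self):
        mol = parse_smiles("CCO")
        elements = sorted(a.element for a in mol.atoms)
        assert elements == ["C", "C", "H", "H", "H", "H", "H", "H", "O"]
        assert mol.dimensionality == "2D"

    def test_phosphonoacetic_formula(self):
        assert hill_formula(parse_smiles("C(C(=O)O)P(=O)(O)O")) == "C2H5O5P"

    def test_alanine_mirror_pair_differs_only_in_parity(self):
        from inchilabel.inchi_engine import compute_inchi

        a = parse_smiles("N[C@@H](C)C(=O)O")
        b = parse_smiles("N[C@H](C)C(=O)O")
        assert sorted(x.element for x in a.atoms) == \
            sorted(x.element for x in b.atoms)
        ia, ib = compute_inchi(a).inchi, compute_inchi(b).inchi
        assert ia != ib
        assert ia.replace("/m0", "/m1") == ib or ia.replace("/m1", "/m0") == ib

    def test_unparsable_smiles(self):
        with pytest.raises(MolfileError):
            parse_smiles("C1CC")  # unmatched ring bond


class TestFormulaAndComponents:
    def test_methane_formula(self):
        assert hill_formula(fx.graph("methane")) == "CH4"

    def test_two_ethanols_before_multiplicity_folding(self):
        mix = union([fx.graph("ethanol"), fx.graph("ethanol")])
        assert hill_formula(mix) == "C2H6O.C2H6O"

    def test_component_count(self):
        assert len(connected_components(fx.graph("ethanol"))) == 1
        mix = fx.mixture("ethanol", "water")
        assert len(connected_components(mix)) == 2

    def test_components_agree_with_bfs_oracle(self, rng):
        def bfs_components(n, edges):
            adj = {i: set() for i in range(1, n + 1)}
            for a, b in edges:
                adj[a].add(b)
                adj[b].add(a)
            seen, comps = set(), []
            for start in range(1, n + 1):
                if start in seen:
                    continue
                queue, comp = [start], set()
                while queue:
                    v = queue.pop()
                    if v in comp:
                        continue
                    comp.add(v)
                    queue.extend(adj[v] - comp)
                seen |= comp
                comps.append(sorted(comp))
            return comps

        from inchilabel.molgraph import Atom, Bond

        for _ in range(100):
            n = rng.randint(1, 14)
            possible = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
            edges = [e for e in possible if rng.random() < 0.15]
            mol = MolGraph(
                [Atom(index=i, element="C") for i in range(1, n + 1)],
                [Bond(a=a, b=b) for a, b in edges],
            )
            assert connected_components(mol) == bfs_components(n, edges)


class TestTransforms:
    def test_identity_permutation(self):
        mol = fx.graph("ethanol")
        same = permute_atoms(mol, {i: i for i in range(1, 10)})
        assert [a.coords for a in same.atoms] == [a.coords for a in mol.atoms]

    def test_permute_then_inverse(self, rng):
        mol = fx.graph("l_leucine")
        perm = fx.random_permutation(len(mol), rng)
        inverse = {v: k for k, v in perm.items()}
        back = permute_atoms(permute_atoms(mol, perm), inverse)
        assert [a.coords for a in back.atoms] == [a.coords for a in mol.atoms]
        assert {b.key for b in back.bonds} == {b.key for b in mol.bonds}

    def test_not_a_bijection(self):
        with pytest.raises(ValueError, match="bijection"):
            permute_atoms(fx.graph("methane"), {i: 1 for i in range(1, 6)})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), name=st.sampled_from(fx.names()))
    def test_hill_formula_invariant_under_permutation(self, seed, name):
        mol = fx.graph(name)
        variant, _ = fx.permuted_copy(mol, random.Random(seed))
        assert hill_formula(variant) == hill_formula(mol)

    def test_mirror_is_involution(self):
        mol = fx.graph("l_leucine")
        assert [a.coords for a in mirror(mirror(mol)).atoms] == \
            [a.coords for a in mol.atoms]

    def test_mirror_preserves_formula(self):
        mol = fx.graph("scyllo_inositol")
        assert hill_formula(mirror(mol)) == hill_formula(mol)

    def test_mirror_2d_without_wedges_rejected(self):
        flat = parse_smiles("C")  # achiral: 2D layout, no wedges
        with pytest.raises(MolfileError, match="wedge"):
            mirror(flat)

    def test_apply_input_labels(self):
        mol = apply_input_labels(fx.graph("water"), "1 OW\n2 HW1\n3 HW2")
        assert [a.input_label for a in mol.atoms] == ["OW", "HW1", "HW2"]
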