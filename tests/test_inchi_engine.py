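"""Engine wrapper, layer parsing, connection graphs, orbit refinement."""

import itertools
import random

import pytest

from inchilabel import fixtures as fx
from inchilabel.inchi_engine import (
    InChIError,
    compute_inchi,
    connection_graph,
    orbit_partition,
    parse_connection_layer,
    parse_layers,
    split_components,
)
from inchilabel.molgraph import parse_smiles, union


class TestComputeInchi:
    def test_ethanol_reference_string(self):
        rec = compute_inchi(fx.graph("ethanol"))
        assert rec.inchi == "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"

    def test_frozen_fixture_identifiers(self, fixture_name):
        rec = compute_inchi(fx.graph(fixture_name))
        assert rec.inchi == fx.expected_inchi(fixture_name)

    def test_smiles_spellings_agree(self):
        a = compute_inchi(parse_smiles("CCO"))
        b = compute_inchi(parse_smiles("C(C)O"))
        assert a.inchi == b.inchi

    def test_methane_canonical_map_single_heavy_atom(self):
        rec = compute_inchi(fx.graph("methane"))
        assert rec.canonical_map == [{1: 1}]

    def test_determinism(self):
        r1 = compute_inchi(fx.graph("l_leucine"))
        r2 = compute_inchi(fx.graph("l_leucine"))
        assert (r1.inchi, r1.auxinfo) == (r2.inchi, r2.auxinfo)

    def test_permutation_leaves_string_and_composes_map(self, rng):
        # The canonical map of a permuted file composes with the permutation
        # up to InChI's own equivalence classes (AuxInfo /E:): a canonical
        # number pinned to a unique atom must follow it exactly; within an
        # equivalence class any member is an admissible image.
        mol = fx.graph("l_leucine")
        base = compute_inchi(mol)
        eq_of = {}
        for cls in base.equivalence[0]:
            for canon in cls:
                eq_of[canon] = cls
        for _ in range(10):
            variant, perm = fx.permuted_copy(mol, rng)
            rec = compute_inchi(variant)
            assert rec.inchi == base.inchi
            for canon, orig in base.canonical_map[0].items():
                admissible = {
                    perm[base.canonical_map[0][c]]
                    for c in eq_of.get(canon, {canon})
                }
                assert rec.canonical_map[0][canon] in admissible


class TestParseLayers:
    def test_methane_has_no_connection_layer(self):
        layers, n = parse_layers("InChI=1S/CH4/h1H4")
        assert layers["formula"] == "CH4"
        assert "c" not in layers
        assert n == 1

    def test_ethanol_layers(self):
        layers, _ = parse_layers(fx.expected_inchi("ethanol"))
        assert layers["c"] == "1-2-3"
        assert layers["h"] == "3H,2H2,1H3"

    def test_multiplier_expansion_from_real_mixture(self):
        mix = union([fx.graph("ethanol"), fx.graph("ethanol")])
        rec = compute_inchi(mix)
        assert rec.inchi.startswith("InChI=1S/2C2H6O/c2*1-2-3/")
        assert rec.formula == ["C2H6O", "C2H6O"]
        assert rec.component_layers[0]["c"] == rec.component_layers[1]["c"] == "1-2-3"

    def test_isotopic_stereo_sublayers_kept_apart(self):
        layers, _ = parse_layers(
            "InChI=1S/C6H13NO2/c1-4(2)3-5(7)6(8)9/h4-5H,3,7H2,1-2H3,(H,8,9)"
            "/t5-/m0/s1/i1D/t4-,5+/m1"
        )
        assert layers["t"] == "5-" and layers["i.t"] == "4-,5+"
        assert layers["m"] == "0" and layers["i.m"] == "1"

    def test_non_standard_prefix_rejected(self):
        with pytest.raises(InChIError, match="standard"):
            parse_layers("InChI=1/CH4/h1H4")

    def test_component_count_mismatch(self):
        with pytest.raises(InChIError, match="components"):
            split_components("1-2-3;1-2", 3)


class TestConnectionGraph:
    @staticmethod
    def _recursive_oracle(text):
        """Independent recursive-descent parse of the /c grammar."""
        tokens = [t for t in
                  itertools.chain.from_iterable(
                      [c] if c in "(),-" else [c]
                      for c in __import__("re").findall(r"\d+|[()\-,]", text))]
        pos = 0
        edges = []
        seen = set()

        def walk(parent):
            nonlocal pos
            current = parent
            while pos < len(tokens):
                tok = tokens[pos]
                if tok == "(":
                    pos += 1
                    walk(current)
                elif tok == ")":
                    pos += 1
                    return
                elif tok == ",":
                    pos += 1
                    current = parent
                elif tok == "-":
                    pos += 1
                else:
                    n = int(tok)
                    pos += 1
                    if current is not None:
                        edges.append(frozenset((current, n)))
                    if n not in seen:
                        seen.add(n)
                        current = n

        walk(None)
        return set(edges)

    def test_ethanol_path_graph(self):
        rec = compute_inchi(fx.graph("ethanol"))
        g = connection_graph(rec, 0)
        assert set(g.edges) == {(1, 2), (2, 3)}

    def test_single_heavy_atom_edgeless(self):
        rec = compute_inchi(fx.graph("methane"))
        g = connection_graph(rec, 0)
        assert list(g.nodes) == [1] and not list(g.edges)

    @pytest.mark.parametrize(
        "layer", ["1-2(-3)-4", "1-4(2)3-5(7)6(8)9", "1-7-5-3-2-4-6-7",
                  "7-1-2(8)4(10)6(12)5(11)3(1)9", "1-2(3,4)5"]
    )
    def test_matches_recursive_descent_oracle(self, layer):
        edges = {frozenset(e) for e in parse_connection_layer(layer)}
        assert edges == self._recursive_oracle(layer)

    def test_fixture_layers_reconnect_heavy_graph(self, fixture_name):
        # /c edges mapped through the canonical numbering equal the input
        # heavy-atom bonds — the graph-correspondence check of the protocol
        mol = fx.graph(fixture_name)
        rec = compute_inchi(mol)
        cmap = rec.canonical_map[0]
        g = connection_graph(rec, 0)
        mapped = {frozenset((cmap[a], cmap[b])) for a, b in g.edges}
        heavy = set(mol.heavy_indices())
        expected = {
            b.key for b in mol.bonds if b.a in heavy and b.b in heavy
        }
        assert mapped == expected


def exhaustive_orbits(mol):
    """Brute-force automorphism orbits (bond orders ignored, as in the
    identifier's skeleton): enumerate candidate maps within refinement
    classes and keep the bond-preserving ones."""
    part = orbit_partition(mol)
    classes = [sorted(c) for c in part.classes]
    adjacency = {
        a.index: frozenset(mol.neighbors(a.index)) for a in mol.atoms
    }
    edges = {b.key for b in mol.bonds}
    orbit_pairs = set()
    for perms in itertools.product(
        *[itertools.permutations(c) for c in classes]
    ):
        mapping = {}
        for cls, perm in zip(classes, perms):
            mapping.update(dict(zip(cls, perm)))
        if {frozenset((mapping[a], mapping[b])) for a, b in
                (tuple(e) for e in edges)} == edges:
            for i, j in mapping.items():
                orbit_pairs.add((i, j))
    # transitive closure into orbits
    orbits = {i: {i} for i in adjacency}
    for i, j in orbit_pairs:
        merged = orbits[i] | orbits[j]
        for k in merged:
            orbits[k] = merged
    return {frozenset(v) for v in orbits.values()}


class TestOrbitPartition:
    def test_benzene_single_carbon_and_hydrogen_classes(self):
        part = orbit_partition(fx.graph("benzene"))
        sizes = sorted(len(c) for c in part.classes)
        assert sizes == [6, 6]

    def test_leucine_methyl_carbons_share_class(self):
        mol = fx.graph("l_leucine")
        part = orbit_partition(mol)
        methyls = [
            i for i in mol.heavy_indices()
            if mol.atom(i).element == "C" and len(mol.hydrogen_neighbors(i)) == 3
        ]
        assert len(methyls) == 2
        assert part.class_of(methyls[0]) == part.class_of(methyls[1])

    def test_methane_hydrogen_class_of_four(self):
        part = orbit_partition(fx.graph("methane"))
        assert frozenset({2, 3, 4, 5}) in part.classes

    def test_never_merges_different_elements(self, fixture_name):
        mol = fx.graph(fixture_name)
        for cls in orbit_partition(mol).classes:
            assert len({mol.atom(i).element for i in cls}) == 1

    def test_invariant_under_permutation(self, rng):
        mol = fx.graph("toluene")
        base = orbit_partition(mol)
        variant, perm = fx.permuted_copy(mol, rng)
        image = {
            frozenset(perm[i] for i in cls) for cls in base.classes
        }
        assert image == set(orbit_partition(variant).classes)

    def test_matches_exhaustive_search_on_small_fixtures(self):
        for name in fx.names():
            mol = fx.graph(name)
            if len(mol.atoms) > 14:
                continue
            part = {frozenset(c) for c in orbit_partition(mol).classes}
            assert part == exhaustive_orbits(mol), name
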