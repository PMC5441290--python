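import random

import pytest

from inchilabel import fixtures as fx
from inchilabel.inchi_engine import InChIEngine


@pytest.fixture
def engine():
    """Fresh engine so tests can count invocations in isolation."""
    return InChIEngine()


@pytest.fixture
def rng():
    return random.Random(20170523)


@pytest.fixture(params=fx.names())
def fixture_name(request):
    return request.param


METHANE_MOLBLOCK = """methane


  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300    0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300   -0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300    0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300   -0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
"""


@pytest.fixture
def methane_molblock():
    return METHANE_MOLBLOCK


def assert_label_stability(mol, base, permuted_result, perm):
    """Shared oracle: atoms outside interchangeable sets keep their label,
    interchangeable groups map onto themselves, identical-component blocks
    may swap wholesale."""
    exempt = set(base.labels.interchangeable_labels())
    swap_blocks = {
        o for grp in base.labels.interchangeable_blocks for o in grp
    }
    for a in mol.atoms:
        l0 = base.labels.forward[a.index]
        l1 = permuted_result.labels.forward[perm[a.index]]
        if base.labels.component_of[a.index] in swap_blocks:
            continue
        if l0 not in exempt:
            assert l1 == l0, f"atom {a.index}: {l0} -> {l1}"
    for s in base.labels.interchangeable_sets:
        if any(
            base.labels.component_of[base.labels.inverse[l]] in swap_blocks
            for l in s
        ):
            continue
        image = {
            permuted_result.labels.forward[perm[base.labels.inverse[l]]]
            for l in s
        }
        assert image == set(s), f"interchangeable set moved: {sorted(s)}"
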