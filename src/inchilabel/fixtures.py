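"""Embedded fixture set and seeded variant generators.

The molecules below exercise every branch of the labeling protocol:
methane and water (fully homotopic hydrogens), ethanol (methyl rotor plus a
hydroxyl), glycine (enantiotopic alpha hydrogens, mobile carboxyl
hydrogen), acetamide (rigid primary amide NH2), L-leucine (a chiral center,
a diastereotopic CH2 and two diastereotopic methyls), phosphonoacetic acid
(two mobile-hydrogen groups), toluene and benzene (ring symmetry),
myo- and scyllo-inositol (meso ring stereochemistry, scyllo maximally
symmetric), and the acetone / propen-2-ol keto-enol tautomer pair.

Coordinates were generated once with a seeded distance-geometry embedding
followed by MMFF minimization and are frozen here so that every expected
identifier in the test-suite refers to exact bytes.  The generators at the
bottom derive permuted, mirrored, relabeled and mixture variants
deterministically from a caller-supplied seed.
"""

from __future__ import annotations

import random

from .molgraph import (
    MolGraph,
    apply_input_labels,
    mirror,
    parse_molfile,
    permute_atoms,
    union,
    write_molblock,
)

__all__ = [
    "names",
    "chiral_names",
    "smiles",
    "molblock",
    "graph",
    "expected_inchi",
    "permuted_copy",
    "mirrored_copy",
    "relabeled_copy",
    "mixture",
    "write_fixture_set",
    "MANIFEST",
]

_SMILES = {
    'methane': 'C',
    'water': 'O',
    'ethanol': 'CCO',
    'glycine': 'NCC(=O)O',
    'acetamide': 'CC(N)=O',
    'l_leucine': 'CC(C)C[C@@H](C(=O)O)N',
    'phosphonoacetic_acid': 'C(C(=O)O)P(=O)(O)O',
    'toluene': 'Cc1ccccc1',
    'benzene': 'c1ccccc1',
    'myo_inositol': 'O[C@H]1[C@H](O)[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O',
    'scyllo_inositol': 'O[C@H]1[C@H](O)[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O',
    'acetone': 'CC(C)=O',
    'propen2ol': 'CC(=C)O',
}

_MOLBLOCKS = {
    'methane': """\
methane
  inchilabel fixture

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000   -0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8633   -0.6654   -0.0705 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.2641    0.9824   -0.3976 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2991    0.0989    1.0458 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8283   -0.4159   -0.5778 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
""",
    'water': """\
water
  inchilabel fixture

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0060    0.3978    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7664   -0.1874    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.7604   -0.2104    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
M  END
""",
    'ethanol': """\
ethanol
  inchilabel fixture

  9  8  0  0  0  0  0  0  0  0999 V2000
   -0.8947   -0.1210    0.0515 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5974   -0.3387   -0.0915 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3039    0.7544    0.4766 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1676   -0.0036    1.1053 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2029    0.7960   -0.4613 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4534   -0.9629   -0.3668 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.8814   -0.4315   -1.1441 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.9030   -1.2504    0.4300 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0330    1.5578    0.0005 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
  2  7  1  0
  2  8  1  0
  3  9  1  0
M  END
""",
    'glycine': """\
glycine
  inchilabel fixture

 10  9  0  0  0  0  0  0  0  0999 V2000
   -1.5212    0.4040    0.3431 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3968    0.0093   -0.5190 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.9039   -0.0388    0.2705 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0266   -0.1934    1.4761 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.9932    0.0459   -0.5205 O   0  0  0  0  0  0  0  0  0  0  0  0
   -2.3983    0.1519   -0.1073 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4692   -0.1320    1.2122 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5762   -0.9857   -0.9372 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3032    0.7381   -1.3291 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.7412    0.0007    0.1114 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  3  5  1  0
  1  6  1  0
  1  7  1  0
  2  8  1  0
  2  9  1  0
  5 10  1  0
M  END
""",
    'acetamide': """\
acetamide
  inchilabel fixture

  9  8  0  0  0  0  0  0  0  0999 V2000
    1.0359   -0.0092    0.3911 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1548    0.4115   -0.4221 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3144   -0.2481   -0.1490 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1085    1.2881   -1.2766 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.7665   -0.7582    1.1409 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.7915   -0.4347   -0.2746 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.4446    0.8648    0.9052 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1143   -0.0279   -0.7285 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3467   -1.0862    0.4135 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  2  0
  1  5  1  0
  1  6  1  0
  1  7  1  0
  3  8  1  0
  3  9  1  0
M  END
""",
    'l_leucine': """\
l_leucine
  inchilabel fixture

 22 21  0  0  0  0  0  0  0  0999 V2000
   -1.5951   -0.0581    1.3846 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0945   -0.6319    0.0577 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2911   -0.9748   -0.8353 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1546    0.3416   -0.6875 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.1622    0.6599    0.0362 C   0  0  1  0  0  0  0  0  0  0  0  0
    2.1421   -0.5261    0.0343 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9028   -1.7002   -0.1929 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.3983   -0.1518    0.3842 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.8009    1.8138   -0.6426 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7773    0.0689    2.0996 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.3250   -0.7313    1.8475 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0782    0.9142    1.2404 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5657   -1.5673    0.2698 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.9550   -1.6907   -0.3390 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9580   -1.4276   -1.7752 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8765   -0.0812   -1.0771 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0744   -0.0770   -1.6774 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7061    1.2751   -0.8674 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.9857    0.9346    1.0804 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.9070   -0.9870    0.3203 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.7292    1.9375   -0.2299 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2746    2.6594   -0.4309 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  2  0
  6  8  1  0
  5  9  1  0
  1 10  1  0
  1 11  1  0
  1 12  1  0
  2 13  1  0
  3 14  1  0
  3 15  1  0
  3 16  1  0
  4 17  1  0
  4 18  1  0
  5 19  1  1
  8 20  1  0
  9 21  1  0
  9 22  1  0
M  END
""",
    'phosphonoacetic_acid': """\
phosphonoacetic_acid
  inchilabel fixture

 13 12  0  0  0  0  0  0  0  0999 V2000
    0.0974    0.5126   -0.5125 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2739    0.8824    0.3157 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.6987    0.3266    1.3106 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.8712    2.0052   -0.1398 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5680   -1.0667   -0.0987 P   0  0  0  0  0  0  0  0  0  0  0  0
    0.3233   -2.2564   -0.2086 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8878   -1.2112   -1.0061 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2735   -0.9287    1.3323 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.4079    0.4964   -1.5624 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6662    1.2868   -0.3878 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.6189    2.1462    0.4808 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.3674   -0.3854   -1.1990 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5285   -1.8079    1.6757 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  2  4  1  0
  1  5  1  0
  5  6  2  0
  5  7  1  0
  5  8  1  0
  1  9  1  0
  1 10  1  0
  4 11  1  0
  7 12  1  0
  8 13  1  0
M  END
""",
    'toluene': """\
toluene
  inchilabel fixture

 15 15  0  0  0  0  0  0  0  0999 V2000
    2.2212    0.0090    0.0054 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7217    0.0012   -0.0230 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0072    1.2038   -0.0889 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3887    1.1981   -0.0836 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0817   -0.0082   -0.0018 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3794   -1.2092    0.0789 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0166   -1.2048    0.0737 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.6252   -0.9035   -0.4456 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.6184    0.8556   -0.5644 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.5755    0.0801    1.0384 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.5346    2.1533   -0.1456 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9352    2.1358   -0.1403 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1683   -0.0121    0.0032 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9186   -2.1501    0.1489 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.5513   -2.1491    0.1447 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  7  2  1  0
  1  8  1  0
  1  9  1  0
  1 10  1  0
  3 11  1  0
  4 12  1  0
  5 13  1  0
  6 14  1  0
  7 15  1  0
M  END
""",
    'benzene': """\
benzene
  inchilabel fixture

 12 12  0  0  0  0  0  0  0  0999 V2000
   -0.4379    1.3241   -0.0246 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3657    0.2825   -0.0246 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9278   -1.0415   -0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.4379   -1.3241    0.0246 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3657   -0.2825    0.0247 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.9278    1.0415    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7791    2.3557   -0.0438 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.4297    0.5027   -0.0439 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6506   -1.8530   -0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.7791   -2.3557    0.0438 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.4297   -0.5027    0.0439 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.6506    1.8530    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  1  7  1  0
  2  8  1  0
  3  9  1  0
  4 10  1  0
  5 11  1  0
  6 12  1  0
M  END
""",
    'myo_inositol': """\
myo_inositol
  inchilabel fixture

 24 24  0  0  0  0  0  0  0  0999 V2000
    1.0537   -0.8690   -1.7694 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.2480   -0.4161   -0.4199 C   0  0  1  0  0  0  0  0  0  0  0  0
    0.9957    1.1126   -0.3734 C   0  0  2  0  0  0  0  0  0  0  0  0
    1.9336    1.7629    0.5007 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4306    1.4999    0.0655 C   0  0  2  0  0  0  0  0  0  0  0  0
   -0.4793    1.6513    1.4915 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4191    0.4304   -0.3963 C   0  0  2  0  0  0  0  0  0  0  0  0
   -2.7759    0.8530   -0.2053 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1650   -0.8972    0.3454 C   0  0  1  0  0  0  0  0  0  0  0  0
   -1.8455   -1.9426   -0.3816 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.3363   -1.2424    0.5074 C   0  0  2  0  0  0  0  0  0  0  0  0
    0.7362   -1.0734    1.8688 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.5012   -1.7314   -1.8568 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.2981   -0.6047   -0.1647 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1578    1.5232   -1.3785 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.7973    1.7585    0.0505 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6960    2.4802   -0.3454 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.4172    1.9472    1.7508 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3227    0.2856   -1.4790 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3095    0.0418   -0.1122 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6487   -0.8706    1.3292 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4834   -1.9555   -1.2860 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.4701   -2.3073    0.2785 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.6304   -1.4365    1.9804 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  3  5  1  0
  5  6  1  0
  5  7  1  0
  7  8  1  0
  7  9  1  0
  9 10  1  0
  9 11  1  0
 11 12  1  0
 11  2  1  0
  1 13  1  0
  2 14  1  1
  3 15  1  6
  4 16  1  0
  5 17  1  6
  6 18  1  0
  7 19  1  6
  8 20  1  0
  9 21  1  1
 10 22  1  0
 11 23  1  6
 12 24  1  0
M  END
""",
    'scyllo_inositol': """\
scyllo_inositol
  inchilabel fixture

 24 24  0  0  0  0  0  0  0  0999 V2000
    1.3281   -0.7428   -1.8070 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.4436   -0.2134   -0.4787 C   0  0  1  0  0  0  0  0  0  0  0  0
    0.7943    1.1928   -0.4759 C   0  0  2  0  0  0  0  0  0  0  0  0
    1.6085    2.1701    0.1885 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5927    1.2138    0.1813 C   0  0  1  0  0  0  0  0  0  0  0  0
   -1.3275    2.3700   -0.2577 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3616   -0.0445   -0.2047 C   0  0  2  0  0  0  0  0  0  0  0  0
   -2.7287    0.0498    0.2245 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7213   -1.2750    0.4507 C   0  0  1  0  0  0  0  0  0  0  0  0
   -1.1135   -2.4515   -0.2698 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.8177   -1.1942    0.5352 C   0  0  2  0  0  0  0  0  0  0  0  0
    1.2086   -0.7904    1.8527 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.6431   -1.6650   -1.7955 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.5153   -0.1143   -0.2687 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6994    1.5542   -1.5083 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.4766    2.1668   -0.2530 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5230    1.3081    1.2718 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7395    3.1282   -0.0689 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4060   -0.1531   -1.2953 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.9817    0.9769    0.0290 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1323   -1.4018    1.4604 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0871   -2.3958   -0.3469 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2437   -2.1916    0.3700 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.9361   -1.4974    2.4662 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  3  5  1  0
  5  6  1  0
  5  7  1  0
  7  8  1  0
  7  9  1  0
  9 10  1  0
  9 11  1  0
 11 12  1  0
 11  2  1  0
  1 13  1  0
  2 14  1  1
  3 15  1  6
  4 16  1  0
  5 17  1  1
  6 18  1  0
  7 19  1  6
  8 20  1  0
  9 21  1  1
 10 22  1  0
 11 23  1  6
 12 24  1  0
M  END
""",
    'acetone': """\
acetone
  inchilabel fixture

 10  9  0  0  0  0  0  0  0  0999 V2000
   -1.2857   -0.1250    0.0290 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0350    0.3579   -0.5065 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2668   -0.0687    0.2452 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.1043    1.0665   -1.5096 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3072   -1.2175    0.0202 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4264    0.2472    1.0467 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0980    0.2498   -0.6000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2180    0.3055    1.2707 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.3372   -1.1592    0.2441 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.1560    0.3435   -0.2397 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  2  0
  1  5  1  0
  1  6  1  0
  1  7  1  0
  3  8  1  0
  3  9  1  0
  3 10  1  0
M  END
""",
    'propen2ol': """\
propen2ol
  inchilabel fixture

 10  9  0  0  0  0  0  0  0  0999 V2000
    1.2616   -0.2049    0.1785 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2157   -0.1813   -0.0596 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9554    0.9334   -0.0305 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7721   -1.4144   -0.3164 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.7793   -0.6062   -0.6986 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.6615    0.7945    0.3783 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.4955   -0.8400    1.0389 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5020    1.8988    0.1735 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0250    0.9230   -0.2066 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7276   -1.3029   -0.4575 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  2  4  1  0
  1  5  1  0
  1  6  1  0
  1  7  1  0
  3  8  1  0
  3  9  1  0
  4 10  1  0
M  END
""",
}

_EXPECTED_INCHI = {
    'methane': 'InChI=1S/CH4/h1H4',
    'water': 'InChI=1S/H2O/h1H2',
    'ethanol': 'InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3',
    'glycine': 'InChI=1S/C2H5NO2/c3-1-2(4)5/h1,3H2,(H,4,5)',
    'acetamide': 'InChI=1S/C2H5NO/c1-2(3)4/h1H3,(H2,3,4)',
    'l_leucine': 'InChI=1S/C6H13NO2/c1-4(2)3-5(7)6(8)9/h4-5H,3,7H2,1-2H3,(H,8,9)/t5-/m0/s1',
    'phosphonoacetic_acid': 'InChI=1S/C2H5O5P/c3-2(4)1-8(5,6)7/h1H2,(H,3,4)(H2,5,6,7)',
    'toluene': 'InChI=1S/C7H8/c1-7-5-3-2-4-6-7/h2-6H,1H3',
    'benzene': 'InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H',
    'myo_inositol': 'InChI=1S/C6H12O6/c7-1-2(8)4(10)6(12)5(11)3(1)9/h1-12H/t1-,2-,3-,4+,5-,6-',
    'scyllo_inositol': 'InChI=1S/C6H12O6/c7-1-2(8)4(10)6(12)5(11)3(1)9/h1-12H/t1-,2-,3+,4+,5-,6-',
    'acetone': 'InChI=1S/C3H6O/c1-3(2)4/h1-2H3',
    'propen2ol': 'InChI=1S/C3H6O/c1-3(2)4/h4H,1H2,2H3',
}

MANIFEST = tuple(sorted(_MOLBLOCKS))

# fixtures whose standard InChI carries tetrahedral stereo layers
_CHIRAL = ("l_leucine", "myo_inositol", "scyllo_inositol")


def names() -> tuple[str, ...]:
    return MANIFEST


def chiral_names() -> tuple[str, ...]:
    return _CHIRAL


def smiles(name: str) -> str:
    return _SMILES[name]


def molblock(name: str) -> str:
    return _MOLBLOCKS[name]


def graph(name: str) -> MolGraph:
    return parse_molfile(_MOLBLOCKS[name])[0]


def expected_inchi(name: str) -> str:
    """Frozen engine output for the fixture bytes (regression anchor)."""
    return _EXPECTED_INCHI[name]


def random_permutation(n: int, rng: random.Random) -> dict[int, int]:
    targets = list(range(1, n + 1))
    rng.shuffle(targets)
    return {i + 1: t for i, t in enumerate(targets)}


def permuted_copy(mol: MolGraph, rng: random.Random) -> tuple[MolGraph, dict[int, int]]:
    """Random atom-order variant plus the old->new index map used."""
    perm = random_permutation(len(mol), rng)
    return permute_atoms(mol, perm), perm


def mirrored_copy(mol: MolGraph) -> MolGraph:
    return mirror(mol)


def relabeled_copy(mol: MolGraph, scheme: str = "db") -> MolGraph:
    """Attach database-style free-text input labels (e.g. "db7") to a copy."""
    text = "\n".join(f"{a.index} {scheme}{a.index}" for a in mol.atoms)
    return apply_input_labels(mol, text)


def mixture(*fixture_names: str) -> MolGraph:
    """One disconnected record concatenating the named fixtures."""
    mols = [graph(n) for n in fixture_names]
    return union(mols, title="+".join(fixture_names))


def write_fixture_set(directory, seed: int = 0) -> list[str]:
    """Write the embedded set plus seeded variants; byte-deterministic."""
    import os

    rng = random.Random(seed)
    written: list[str] = []

    def emit(fname: str, text: str) -> None:
        path = os.path.join(directory, fname)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        written.append(fname)

    os.makedirs(directory, exist_ok=True)
    for name in MANIFEST:
        emit(f"{name}.mol", molblock(name))
    for name in ("ethanol", "l_leucine", "scyllo_inositol"):
        variant, _ = permuted_copy(graph(name), rng)
        emit(f"{name}_permuted.mol", write_molblock(variant))
    for name in _CHIRAL:
        emit(f"{name}_mirror.mol", write_molblock(mirrored_copy(graph(name))))
    emit("ethanol_water.mol", write_molblock(mixture("ethanol", "water")))
    emit("ethanol_x2.mol", write_molblock(mixture("ethanol", "ethanol")))
    tautomers = molblock("acetone").rstrip("\n") + "\n$$$$\n" + \
        molblock("propen2ol").rstrip("\n") + "\n$$$$\n"
    emit("keto_enol.sdf", tautomers)
    return written
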