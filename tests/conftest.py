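import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make oracles importable

from helvepan import synth  # noqa: E402


@pytest.fixture
def three_copy_genome():
    """20 kb genome with one 3-copy planted family (600 bp, 2% mutation)."""
    spec = synth.RepeatPlantSpec(
        backbone_length=20_000, families=((3, 600, 0.02),), seed=7
    )
    return synth.make_repeat_genome(spec)


@pytest.fixture
def small_strain_family():
    """5 strains, 30 core / 8 accessory / 2 unique clusters, low divergence."""
    spec = synth.StrainFamilySpec(
        n_strains=5,
        n_core=30,
        n_accessory=8,
        n_unique_per_strain=2,
        within_mutation=0.002,
        seed=11,
    )
    return synth.make_strain_family(spec)
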