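import numpy as np
import pytest

from crossfam.family import Amplicon, GeneFamily, Guide
from crossfam.simulate import FamilySimSpec, simulate_family


def make_family(members):
    """Build a GeneFamily from (name, amplicon_seq, guide_seq) triples."""
    return GeneFamily(
        name="T",
        members=[
            (Amplicon(name=n, sequence=s, family="T"),
             Guide(name=n, sequence=g, family_member=n))
            for n, s, g in members
        ],
    )


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet)) for _ in range(length))


@pytest.fixture(scope="session")
def sim_family():
    """A reproducible 2-member family with one planted d=10 off-target."""
    spec = FamilySimSpec(seed=11, planted_offtargets=(("S1", "S2", 10),))
    return simulate_family(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
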