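import numpy as np
import pytest

from copiakit.reference import FAMILY_TABLE, build_reference_templates
from copiakit.synthetic import implant_copies, random_genome


@pytest.fixture(scope="session")
def templates():
    """Lineage-structured templates for the nine-family structural table."""
    return build_reference_templates(11)


@pytest.fixture(scope="session")
def jc1(templates):
    return templates["Jc1"]


@pytest.fixture(scope="session")
def genome9(templates):
    """150 kb genome with one zero-divergence copy of each family."""
    g = random_genome(150_000, seed=21)
    for i, spec in enumerate(FAMILY_TABLE):
        implant_copies(g, templates[spec.name], 1, divergence=0.0, seed=100 + i)
    return g


@pytest.fixture(scope="session")
def genome5(jc1):
    """200 kb genome with five zero-divergence Jc1 copies."""
    g = random_genome(200_000, seed=2)
    implant_copies(g, jc1, 5, divergence=0.0, seed=4)
    return g


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
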