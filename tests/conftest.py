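import numpy as np
import pytest

from znsite import fixtures
from znsite.postprocess import PipelineConfig
from znsite.template_library import build_inverted_index


@pytest.fixture(scope="session")
def fixture_bundle():
    """(structures, library) built from the default specs, seed 1."""
    return fixtures.make_fixture_library(seed=1)


@pytest.fixture(scope="session")
def library(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture(scope="session")
def fixture_structures(fixture_bundle):
    return fixture_bundle[0]


@pytest.fixture(scope="session")
def index(library):
    return build_inverted_index(library)


@pytest.fixture
def config(library):
    return PipelineConfig(library=library)


@pytest.fixture
def ideal_hhec():
    """One geometrically exact His-His-Glu-Cys tetrahedral site at a known
    ion position."""
    spec = fixtures.SiteSpec(("HIS", "HIS", "GLU", "CYS"), "tetrahedral")
    return fixtures.make_ideal_site(spec, zinc_coord=(1.0, -2.0, 3.0), structure_id="hhec")


def assert_allclose(a, b, atol=1e-8):
    np.testing.assert_allclose(a, b, atol=atol)
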