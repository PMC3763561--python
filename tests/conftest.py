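import pytest

from unskit.parts_model import make_fixture_library
from unskit.uns_designer import DesignConfig, generate_candidates, select_orthogonal_set


@pytest.fixture(scope="session")
def fast_config():
    """Small candidate pool: enough for set selection, quick to sample."""
    return DesignConfig(rng_seed=11, n_candidates=60)


@pytest.fixture(scope="session")
def uns6(fast_config):
    """A designed 6+X set (the 5-TU worked example needs UNS1..6, X)."""
    cands = generate_candidates(fast_config)
    return select_orthogonal_set(cands, 6, fast_config)


@pytest.fixture(scope="session")
def lib5():
    """A 5-TU fixture library at realistic part sizes."""
    return make_fixture_library(1, 5)


@pytest.fixture(scope="session")
def plan5(lib5):
    from unskit.assembly_planner import design_from_library, plan_assembly

    return plan_assembly(design_from_library(lib5), lib5.uns_set, lib5)
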