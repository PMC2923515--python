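import logging

import pytest

from ferlinkit.library import build_default_library
from ferlinkit.simulate import PhylogenySpec, default_template, simulate_family


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Keep expected pipeline warnings out of test output."""
    logger = logging.getLogger("ferlinkit")
    level = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(level)


@pytest.fixture(scope="session")
def library():
    return build_default_library()


@pytest.fixture(scope="session")
def library_map(library):
    return {s.name: s for s in library}


@pytest.fixture(scope="session")
def templates():
    return default_template(1, "A"), default_template(2, "A")


@pytest.fixture(scope="session")
def perfect_family(templates):
    """Undiverged family: every domain an exact consensus copy."""
    t1, t2 = templates
    return simulate_family(
        t1, t2, PhylogenySpec("(sp1:0.0,sp2:0.0);"), rate_scale=0.0, seed=5,
        ancestral_divergence=0.0,
    )


@pytest.fixture(scope="session")
def diverged_family(templates):
    t1, t2 = templates
    return simulate_family(
        t1, t2, PhylogenySpec("((s1:0.08,s2:0.08):0.05,(s3:0.08,s4:0.08):0.05);"),
        seed=11,
    )
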