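import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rnatangle.fixtures import FixtureSpec, make_clean, make_entangled, make_helix


@pytest.fixture(scope="session")
def helix8():
    return make_helix(8)


@pytest.fixture(scope="session")
def clean_fixture():
    return make_clean(FixtureSpec("clean", seed=1))


@pytest.fixture(scope="session")
def ls_fixture():
    """A deep L(S) lasso (strand threaded 8 nt through a hairpin loop)."""
    return make_entangled(FixtureSpec("L(S)", seed=1))


@pytest.fixture(scope="session")
def ll_interlace_fixture():
    return make_entangled(FixtureSpec("L&L", seed=1))
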