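import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py importable

from blanchsim import effective_properties, solve_heat_transfer
from blanchsim import params as P


@pytest.fixture(scope="session")
def bean_props():
    return effective_properties(P.default_composition())


@pytest.fixture(scope="session")
def geometry():
    return P.default_geometry()


@pytest.fixture(scope="session")
def hot_field(geometry, bean_props):
    """Solved 92 C constant-bath field, 7 min, default 5-cell bean."""
    return solve_heat_transfer(geometry, bean_props, P.default_bath(92.0, 420.0))
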