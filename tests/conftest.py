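import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from termkin import load_rf3_kinetics, load_scheme_rates


@pytest.fixture(scope="session")
def rf1_20c():
    return load_scheme_rates("RF1", 20)


@pytest.fixture(scope="session")
def rf2_20c():
    return load_scheme_rates("RF2", 20)


@pytest.fixture(scope="session")
def rf3_gtp():
    return load_rf3_kinetics("GTP")


@pytest.fixture(scope="session")
def rf3_gdp():
    return load_rf3_kinetics("GDP")
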