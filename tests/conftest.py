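import numpy as np
import pytest

from chargecorr import FixtureRecipe, SoluteAtom, SoluteStructure, assign_radii
from chargecorr.fixtures import build_complex
from chargecorr.io import load_benchmark_ledgers


@pytest.fixture(scope="session")
def benchmark_ledgers():
    ledgers, flagged = load_benchmark_ledgers()
    assert not flagged, flagged
    return ledgers


@pytest.fixture(scope="session")
def ledger_index(benchmark_ledgers):
    return {(led.guest, led.environment, led.scheme_tag): led
            for led in benchmark_ledgers}


def make_ion(radius=0.2, charge=1.0):
    atom = SoluteAtom(name="ION", element="C", position=np.zeros(3), charge=charge,
                      radius=radius, is_polar_hydrogen=False, group="guest")
    return SoluteStructure([atom], [], set(), "ion")


@pytest.fixture
def ion():
    return make_ion()


@pytest.fixture(scope="session")
def mam_cneg():
    return assign_radii(build_complex(FixtureRecipe(host="CNEG", guest="MAM", seed=11)))


@pytest.fixture(scope="session")
def mam_capo():
    return assign_radii(build_complex(FixtureRecipe(host="CAPO", guest="MAM", seed=11)))
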