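import pytest

import gestpbpk as g


@pytest.fixture(scope="session")
def escitalopram():
    compound, fetal = g.load_compound()
    return compound


@pytest.fixture(scope="session")
def fetal_params():
    _, fetal = g.load_compound()
    return fetal


@pytest.fixture(scope="session")
def phys0():
    return g.build_physiology(0.0)


@pytest.fixture(scope="session")
def regimen10():
    return g.DoseRegimen(dose=10.0, interval=24.0, n_doses=10)


@pytest.fixture(scope="session")
def profile10_gw0(escitalopram, phys0, regimen10):
    """Default-individual 10 mg x 10 d profile at gestational week 0."""
    return g.simulate_individual(escitalopram, phys0, regimen10)
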