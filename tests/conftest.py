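import pytest

from hlcur import synthetic_data
from hlcur.acmg_engine import classify_table


@pytest.fixture(scope="session")
def table2():
    table = synthetic_data.load_fixture("table2")
    classify_table(table)
    return table


@pytest.fixture(scope="session")
def table3():
    fixture = synthetic_data.load_fixture("table3")
    classify_table(fixture.variants)
    return fixture


@pytest.fixture(scope="session")
def panel():
    return synthetic_data.load_fixture("panel")


@pytest.fixture()
def helix_pair():
    spec = synthetic_data.HingeHelixSpec(hinge_angle_deg=30.0, noise_sd=0.1, seed=11)
    return synthetic_data.generate_helix_pair(spec)
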