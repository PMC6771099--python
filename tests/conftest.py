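import pytest

import flowregions as fr


@pytest.fixture(scope="session")
def toy3_units():
    return fr.toy3_units()


@pytest.fixture(scope="session")
def toy3_records():
    return fr.toy3_records()


@pytest.fixture(scope="session")
def toy3_od(toy3_units, toy3_records):
    return fr.build_od_matrix(toy3_records, toy3_units)


@pytest.fixture(scope="session")
def drs13_dataset():
    """One realization of the hub-dominated regional scenario."""
    scenario = fr.drs13_like(seed=13)
    units = fr.generate_units(scenario)
    records = fr.generate_admissions(scenario, units)
    od = fr.apply_origin_filter(
        fr.build_od_matrix(records, units), units.hospital_units, 5
    )
    return scenario, units, records, od
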