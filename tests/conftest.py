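import pytest

from cumrisk import datasets


@pytest.fixture(scope="session")
def scallion_obs():
    return datasets.load_scallion_residues()


@pytest.fixture(scope="session")
def tox():
    return datasets.load_tox_profiles()


@pytest.fixture(scope="session")
def category_residues():
    return datasets.load_category_residues()


@pytest.fixture(scope="session")
def mrl_table():
    return datasets.load_mrl_table()


@pytest.fixture(scope="session")
def calibration_curves():
    return datasets.load_calibration_curves()
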