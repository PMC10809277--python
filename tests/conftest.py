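import pytest

from twimcal import (
    BiomolecularClass,
    InstrumentConfig,
    default_curves,
    default_trendlines,
)


@pytest.fixture
def config():
    return InstrumentConfig(edc_coefficient=1.57)


@pytest.fixture
def curves():
    return default_curves()


@pytest.fixture
def trendlines():
    return default_trendlines()


@pytest.fixture
def lipid():
    return BiomolecularClass.LIPID
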