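import pytest

from lexdef import spectra, xsection
from lexdef.attenuation import PhantomSpec


@pytest.fixture(scope="session")
def water():
    return xsection.load_material("water")


@pytest.fixture(scope="session")
def pt():
    return xsection.load_material("pt")


@pytest.fixture(scope="session")
def spectrum_160kv():
    return spectra.tube_spectrum(160)


@pytest.fixture(scope="session")
def spectrum_6mv():
    return spectra.linac_spectrum(6)


@pytest.fixture(scope="session")
def phantom_7mg():
    """Default study phantom: 15-cm water prism, 7 mg/ml Pt in 10-12 cm."""
    return PhantomSpec(pt_mg_per_ml=7.0)
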