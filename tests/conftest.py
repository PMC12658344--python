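import pytest

from pbequiv import load_registry, reference_spectrum


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def spectra():
    return {kvp: reference_spectrum(kvp) for kvp in (80, 100, 120)}


@pytest.fixture(scope="session")
def by_abbr(registry):
    return {c.abbreviation: c for c in registry}
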