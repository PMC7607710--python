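import pytest

from carrierscreen import load_reference_catalogue, load_reference_panel, reference_cohort


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def catalogue(panel):
    return load_reference_catalogue(panel)


@pytest.fixture(scope="session")
def ref():
    """The deterministic bundled cohort (panel, catalogue, 200 individuals,
    57 heterozygous genotype observations)."""
    return reference_cohort()
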