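import pytest

from dlahap.datasets import reference_cohort, toy_library


@pytest.fixture(scope="session")
def library():
    return toy_library()


@pytest.fixture(scope="session")
def cohort_haplotype_counts():
    """Reference cohort matching the per-group haplotype chromosome counts."""
    return reference_cohort("haplotype_counts")


@pytest.fixture(scope="session")
def cohort_dose_counts():
    """Reference cohort matching the genotype-dose counts."""
    return reference_cohort("dose_counts")
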