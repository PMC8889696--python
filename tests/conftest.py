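import numpy as np
import pytest

from genoprev import CaseRecord, GroupAlleleFrequency
from genoprev import datasets as ds


@pytest.fixture(scope="session")
def case_fixture():
    return ds.load_case_fixture()


@pytest.fixture(scope="session")
def catalog_fixture():
    return ds.load_catalog_fixture()


@pytest.fixture(scope="session")
def frequency_fixture():
    return ds.load_frequency_fixture()


@pytest.fixture(scope="session")
def country_fixture():
    return ds.load_country_fixture()


@pytest.fixture(scope="session")
def reference_tables():
    return ds.load_reference_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(20220302)


def make_cases(allele_pairs):
    """Build CaseRecords from a list of (allele_a, allele_b) pairs."""
    return [
        CaseRecord(f"T{i:03d}", "test", a, b) for i, (a, b) in enumerate(allele_pairs)
    ]


def gaf(vid, group, k, n):
    return GroupAlleleFrequency(vid, group, k, n, k / n)
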