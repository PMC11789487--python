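"""Shared fixtures: small synthetic reference sets and simulated libraries."""

import pytest

from ottr_endqc.references import (
    OligoScheme,
    ReferenceConfig,
    length_filter,
    make_synthetic_references,
)

SMALL_LENGTH_COUNTS = {19: 8, 20: 8, 21: 8, 22: 8, 23: 4, 24: 4}


@pytest.fixture(scope="session")
def small_refs():
    """40-entry pool with compact contaminant surrogates (fast tests)."""
    config = ReferenceConfig(
        length_counts=dict(SMALL_LENGTH_COUNTS),
        plasmid_length=800,
        genome_length=2000,
    )
    return make_synthetic_references(config, seed=11)


@pytest.fixture(scope="session")
def small_pool(small_refs):
    return small_refs[0]


@pytest.fixture(scope="session")
def small_contaminants(small_refs):
    return small_refs[1]


@pytest.fixture(scope="session")
def full_refs():
    """Default-size pool (962 entries, 943 in the 19-24 nt mapping range)."""
    return make_synthetic_references(ReferenceConfig(), seed=7)


@pytest.fixture(scope="session")
def full_pool(full_refs):
    return full_refs[0]


@pytest.fixture(scope="session")
def mapping_pool(full_pool):
    return length_filter(full_pool, 19, 24)


@pytest.fixture(scope="session")
def reliable_ids(mapping_pool):
    from ottr_endqc.references import reliable_subset

    return reliable_subset(mapping_pool)


@pytest.fixture()
def scheme():
    return OligoScheme()
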