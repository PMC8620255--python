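"""Shared fixtures: primer sets and seeded synthetic references."""

import pytest

from ampliguide import CladePartition, generate_synthetic_reference, get_primer_pair


@pytest.fixture(scope="session")
def primers():
    return get_primer_pair("universal_V4")


@pytest.fixture(scope="session")
def synthetic_ref():
    """Default study-condition fixture: 5 hosts, 20 micro, 2 specific + 2 shared."""
    return generate_synthetic_reference(seed=42)


@pytest.fixture(scope="session")
def partition(synthetic_ref):
    return CladePartition(
        host_records=list(synthetic_ref.host_records),
        micro_records=list(synthetic_ref.micro_records),
    )


# Concrete instances of the default degenerate V4 primer pair, used to build
# hand-crafted records that the degenerate primers are guaranteed to match.
CONCRETE_FWD = "CCAGCACCCGCGGTAATTCC"  # S->C, Y->C
CONCRETE_REV = "ACTTTCGTTCTTGATTAA"    # Y->T, R->A


@pytest.fixture(scope="session")
def concrete_footprints():
    from ampliguide import revcomp

    return CONCRETE_FWD, revcomp(CONCRETE_REV)
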