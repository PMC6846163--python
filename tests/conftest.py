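"""Shared fixtures: CTM tables built once per session from the repo's engine."""

from __future__ import annotations

import pytest

from nucleoscore import tm_engine


@pytest.fixture(scope="session")
def dist22():
    """Full enumeration of the (2 states, 2 symbols) rule space."""
    return tm_engine.build_distribution(2, 2, cutoff=107, sample_size="all")


@pytest.fixture(scope="session")
def table22(dist22):
    return tm_engine.ctm_table_from_distribution(dist22)


@pytest.fixture(scope="session")
def dist25():
    """Sampled (2 states, 5 symbols) space: 4e6 machines, the desk-scale
    stand-in for the exhaustive tables of the method's reference builds."""
    return tm_engine.build_distribution(2, 5, cutoff=107, sample_size=4_000_000, seed=7)


@pytest.fixture(scope="session")
def table25(dist25):
    return tm_engine.complete_by_symmetry(
        tm_engine.ctm_table_from_distribution(dist25)
    )


@pytest.fixture(scope="session")
def toy_table():
    """Hand-built table with known values for exact BDM/LD algebra."""
    entries = {
        "111111111111": (5.0, 20),
        "121212121212": (6.0, 30),
        "123412341234": (7.5, 25),
        "1234": (2.0, 6),
        "44": (1.0, 2),
        "3": (0.5, 1),
    }
    return tm_engine.CTMTable(5, entries, 12, {"source": "toy"})
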