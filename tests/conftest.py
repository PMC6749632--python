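from __future__ import annotations

import pytest
from hypothesis import settings

from pedcase.pedigree import Individual, Pedigree
from pedcase.simulate import PedigreeSimConfig, simulate_pedigree

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def trio() -> Pedigree:
    """Two unrelated founders and their offspring."""
    return Pedigree(
        [
            Individual("A", sex="male"),
            Individual("B", sex="female"),
            Individual("C", sire="A", dam="B"),
        ]
    )


@pytest.fixture
def fullsib_ped() -> Pedigree:
    """Full sibs C, D and their offspring E (inbred, F = 0.25)."""
    return Pedigree(
        [
            Individual("A", sex="male"),
            Individual("B", sex="female"),
            Individual("C", sire="A", dam="B", sex="male"),
            Individual("D", sire="A", dam="B", sex="female"),
            Individual("E", sire="C", dam="D"),
        ]
    )


@pytest.fixture
def halfsib_ped() -> Pedigree:
    """Half sibs (shared sire only) and their offspring (F = 0.125)."""
    return Pedigree(
        [
            Individual("S", sex="male"),
            Individual("D1", sex="female"),
            Individual("D2", sex="female"),
            Individual("H1", sire="S", dam="D1", sex="male"),
            Individual("H2", sire="S", dam="D2", sex="female"),
            Individual("X", sire="H1", dam="H2"),
        ]
    )


@pytest.fixture(scope="session")
def looped() -> tuple:
    """Mid-size looped pedigree with a cohort, shared across tests."""
    cfg = PedigreeSimConfig(loop_ancestors=10, n_cohort=300, seed=11)
    return simulate_pedigree(cfg)
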