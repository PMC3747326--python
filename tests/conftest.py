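import pytest

from pedgif import Genealogy, Individual, simulate_genealogy, SimulationConfig


def make_genealogy(rows):
    """rows: (id, father, mother, sex) tuples with None for missing parents."""
    return Genealogy(
        Individual(id=i, father_id=f, mother_id=m, sex=s) for i, f, m, s in rows
    )


@pytest.fixture
def sib_pedigree():
    """Two full siblings of unrelated founder parents."""
    return make_genealogy([
        ("F", None, None, "male"),
        ("M", None, None, "female"),
        ("S1", "F", "M", "male"),
        ("S2", "F", "M", "male"),
    ])


@pytest.fixture
def avuncular_pedigree():
    """Uncle U and nephew N through founder grandparents."""
    return make_genealogy([
        ("GF", None, None, "male"),
        ("GM", None, None, "female"),
        ("U", "GF", "GM", "male"),
        ("P", "GF", "GM", "male"),
        ("SP", None, None, "female"),
        ("N", "P", "SP", "male"),
    ])


@pytest.fixture
def cousin_pedigree():
    """First cousins C1, C2 plus C1's child C1R (once removed from C2)."""
    return make_genealogy([
        ("GF", None, None, "male"),
        ("GM", None, None, "female"),
        ("A", "GF", "GM", "male"),
        ("B", "GF", "GM", "female"),
        ("SA", None, None, "female"),
        ("SB", None, None, "male"),
        ("C1", "A", "SA", "male"),
        ("C2", "SB", "B", "male"),
        ("SC", None, None, "female"),
        ("C1R", "C1", "SC", "male"),
    ])


@pytest.fixture
def inbred_pedigree():
    """X is the child of first cousins: self-kinship (1 + 1/16) / 2."""
    return make_genealogy([
        ("GF", None, None, "male"),
        ("GM", None, None, "female"),
        ("A", "GF", "GM", "male"),
        ("B", "GF", "GM", "female"),
        ("SA", None, None, "female"),
        ("SB", None, None, "male"),
        ("C1", "A", "SA", "male"),
        ("C2", "SB", "B", "female"),
        ("X", "C1", "C2", "male"),
    ])


@pytest.fixture(scope="session")
def sim_genealogy():
    """One default-condition synthetic genealogy shared across tests."""
    return simulate_genealogy(SimulationConfig(seed=42))
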