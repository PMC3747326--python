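"""GIF statistic, matching, empirical significance and both tests."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedgif import (
    Individual,
    SUBSET_DEFINITIONS,
    assign_phenotypes,
    build_subset,
    draw_control_sets,
    empirical_p,
    gif_by_distance,
    gif_statistic,
    gif_test,
    match_key,
    null_config,
    overlap_report,
    simulate_genealogy,
    subset_gif_test,
)
from conftest import make_genealogy


@pytest.fixture
def trio():
    """Parent with two children: pairs at distance 1 (x2) and 2 (x1)."""
    return make_genealogy([
        ("P", None, None, "male"),
        ("SP", None, None, "female"),
        ("K1", "P", "SP", "male"),
        ("K2", "P", "SP", "female"),
    ])


# -- statistic -------------------------------------------------------------


def test_gif_single_sibling_pair(sib_pedigree):
    pk = sib_pedigree.all_pairs_kinship(["S1", "S2"])
    assert gif_statistic(pk) == 25000.0


def test_gif_unrelated_individuals(sib_pedigree):
    pk = sib_pedigree.all_pairs_kinship(["F", "M"])
    assert gif_statistic(pk) == 0.0


def test_gif_parent_child_plus_unrelated():
    g = make_genealogy([
        ("P", None, None, "male"),
        ("SP", None, None, "female"),
        ("K1", "P", "SP", "male"),
        ("Z", None, None, "male"),
    ])
    pk = g.all_pairs_kinship(["P", "K1", "Z"])
    assert gif_statistic(pk) == pytest.approx(np.mean([0.25, 0, 0]) * 1e5)


def test_gif_requires_two(sib_pedigree):
    with pytest.raises(ValueError):
        gif_statistic(sib_pedigree.all_pairs_kinship(["S1"]))


def test_by_distance_sibling_pair(sib_pedigree):
    pk = sib_pedigree.all_pairs_kinship(["S1", "S2"])
    assert gif_by_distance(pk) == {2: 25000.0}


def test_by_distance_parent_and_two_children(trio):
    pk = trio.all_pairs_kinship(["P", "K1", "K2"])
    by_d = gif_by_distance(pk)
    assert by_d[1] == pytest.approx(2 * 0.25 / 3 * 1e5)  # two parent/child pairs
    assert by_d[2] == pytest.approx(0.25 / 3 * 1e5)  # the sibling pair


def test_by_distance_sums_to_gif_on_random_sets(sim_genealogy):
    rng = np.random.default_rng(11)
    ids = sorted(sim_genealogy.individuals)
    for _ in range(50):
        sample = [ids[k] for k in rng.choice(len(ids), size=25, replace=False)]
        pk = sim_genealogy.all_pairs_kinship(sample)
        assert sum(gif_by_distance(pk).values()) == pytest.approx(
            gif_statistic(pk), rel=1e-9
        )


# -- matching --------------------------------------------------------------


def test_match_key_cohort_binning():
    ind = Individual(id="A", sex="male", birth_year=1941, birth_in_state=True)
    assert match_key(ind).birth_cohort == 1940
    ind.birth_year = 1939
    assert match_key(ind).birth_cohort == 1935


def test_match_key_missing_variable_signals_exclusion():
    assert match_key(Individual(id="A", sex="male", birth_in_state=True)) is None


def _matched_population(n_strata_members=3):
    """Founder-only genealogy with controlled matching strata."""
    inds = []
    k = 0
    for year in (1940, 1941, 1948):
        for _ in range(n_strata_members):
            inds.append(Individual(
                id=f"P{k}", sex="male", birth_year=year, birth_in_state=True,
            ))
            k += 1
    from pedgif import Genealogy
    return Genealogy(inds)


def test_forced_draw_is_deterministic():
    g = _matched_population(n_strata_members=1)
    cases = ["P0"]
    sets = draw_control_sets(g, cases, ["P0", "P2"], R=5, seed=3)
    # only P0 itself shares the 1940 cohort; P2 (1948) is another stratum
    assert all(s == ["P0"] for s in sets)


def test_control_sets_reproduce_matchkey_multiset(sim_genealogy):
    eligible = sorted(sim_genealogy.ancestral_subset(1972))
    rng = np.random.default_rng(2)
    cases = [eligible[k] for k in rng.choice(len(eligible), size=20, replace=False)]
    sets = draw_control_sets(sim_genealogy, cases, eligible, R=100, seed=9)
    want = collections.Counter(match_key(sim_genealogy[c]) for c in cases)
    for s in sets:
        assert len(s) == len(set(s)) == len(cases)
        assert collections.Counter(match_key(sim_genealogy[c]) for c in s) == want


def test_draw_seed_reproducibility(sim_genealogy):
    eligible = sorted(sim_genealogy.ancestral_subset(1972))
    cases = eligible[:15]
    a = draw_control_sets(sim_genealogy, cases, eligible, R=10, seed=4)
    b = draw_control_sets(sim_genealogy, cases, eligible, R=10, seed=4)
    c = draw_control_sets(sim_genealogy, cases, eligible, R=10, seed=5)
    assert a == b
    assert a != c


def test_exhausted_stratum_raises():
    g = _matched_population(n_strata_members=1)
    with pytest.raises(ValueError, match="stratum"):
        # both 1940-cohort members are cases but the pool excludes them
        draw_control_sets(g, ["P0", "P1"], ["P2"], R=1, seed=0)


# -- empirical significance ------------------------------------------------


@given(
    case=st.floats(0, 1e5, allow_nan=False),
    controls=st.lists(st.floats(0, 1e5, allow_nan=False), min_size=1, max_size=200),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_empirical_p_is_a_valid_count_fraction(case, controls):
    p, below = empirical_p(case, controls)
    R = len(controls)
    assert 0.0 <= p <= 1.0
    assert round(p * R) == pytest.approx(p * R)  # p*R is an integer count
    assert below == (p == 0.0)


@given(year=st.integers(1800, 2000))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_match_key_bins_are_five_year_floors(year):
    key = match_key(Individual(id="A", sex="male", birth_year=year,
                               birth_in_state=True))
    assert key.birth_cohort % 5 == 0
    assert key.birth_cohort <= year < key.birth_cohort + 5


def test_empirical_p_counts_ties_as_exceedances():
    p, below = empirical_p(5.0, [4, 4, 4, 6])
    assert (p, below) == (0.25, False)
    p, _ = empirical_p(5.0, [5, 4, 4, 6])
    assert p == 0.5


def test_empirical_p_below_resolution():
    p, below = empirical_p(10.0, np.zeros(1000))
    assert below and p == 0.0


def test_empirical_p_case_below_all_controls():
    p, below = empirical_p(1.0, np.full(1000, 2.0))
    assert (p, below) == (1.0, False)


# -- tests -----------------------------------------------------------------


def _sim_cohort(seed):
    cfg = null_config(seed=seed)
    g = simulate_genealogy(cfg)
    assign_phenotypes(g, cfg)
    eligible = g.ancestral_subset(1972)
    cases = sorted(i for i in eligible if g[i].attributes.get("is_case"))
    return g, cases, sorted(eligible)


def test_gif_test_reproducible_bitwise():
    g, cases, pool = _sim_cohort(21)
    a = gif_test(g, cases[:10], pool, R=1, seed=6)
    b = gif_test(g, cases[:10], pool, R=1, seed=6)
    assert a.case_gif == b.case_gif
    assert np.array_equal(a.control_gifs, b.control_gifs)
    assert a.by_distance == b.by_distance
    assert (a.empirical_p, a.below_resolution) == (b.empirical_p, b.below_resolution)


def test_subset_gif_preserves_case_gif():
    g, cases, pool = _sim_cohort(22)
    subset = cases[::3]
    classical = gif_test(g, subset, pool, R=20, seed=1)
    subsetwise = subset_gif_test(g, subset, cases, R=20, seed=1)
    assert classical.case_gif == subsetwise.case_gif
    assert classical.n_cases == subsetwise.n_cases


def test_subset_controls_more_related_than_population_controls():
    """Case-drawn controls are more related than population-drawn ones on a
    clustered cohort."""
    from pedgif import power_config

    cfg = power_config(seed=30)
    g = simulate_genealogy(cfg)
    assign_phenotypes(g, cfg)
    eligible = g.ancestral_subset(1972)
    cases = sorted(i for i in eligible if g[i].attributes.get("is_case"))
    subset = cases[::4]
    pop = gif_test(g, subset, sorted(eligible), R=50, seed=2)
    sub = subset_gif_test(g, subset, cases, R=50, seed=2)
    assert sub.mean_control_gif >= pop.mean_control_gif


def test_subset_must_be_contained_in_cases():
    g, cases, pool = _sim_cohort(23)
    outsider = [i for i in pool if i not in cases][0]
    with pytest.raises(ValueError, match="subset"):
        subset_gif_test(g, [cases[0], outsider], cases, R=1, seed=0)


# -- subset construction ---------------------------------------------------


def _case(i, **attrs):
    return Individual(id=i, sex="male", attributes={"is_case": True, **attrs})


@pytest.mark.parametrize(
    "subset, attr, inside, outside",
    [
        ("early_onset", "age_at_diagnosis", 49, 50),
        ("gleason_gt7", "gleason", 8, 7),
        ("short_survival", "survival_months", 9, 10),
        ("long_survival", "survival_months", 240, 239),
        ("high_bmi", "bmi", 30.0, 29.9),
        ("other_primary", "other_primary_count", 1, 0),
    ],
)
def test_subset_boundaries(subset, attr, inside, outside):
    members = build_subset(
        [_case("IN", **{attr: inside}), _case("OUT", **{attr: outside}),
         _case("MISSING")],
        subset,
    )
    assert members == {"IN"}


def test_lethal_subset_requires_flag_and_death_cert_pool():
    cases = [_case("L", cause_of_death_phenotype=True), _case("N")]
    assert build_subset(cases, "lethal") == {"L"}
    assert SUBSET_DEFINITIONS["lethal"].control_pool_rule == "death_certificate_cases"


def test_unknown_subset_name():
    with pytest.raises(ValueError, match="unknown subset"):
        build_subset([], "nope")


def test_overlap_report_percentages():
    a = {f"x{i}" for i in range(60)}
    b = {f"x{i}" for i in range(40)} | {f"y{i}" for i in range(160)}
    df = overlap_report({"a": a, "b": b})
    row = df[(df.subset == "a") & (df.denominator == "b")].iloc[0]
    assert row.n_overlap == 40 and row.n_denominator == 200
    assert row.percent == 20.0
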