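"""Genealogical Index of Familiality (GIF) and SubsetGIF tests.

The GIF of a set of individuals is the mean Malécot kinship over all
unordered pairs in the set, scaled by 10**5 so typical population values
land near the single digits.  Excess relatedness is tested empirically: the
case GIF is compared against the GIF of ``R`` control sets, each matched
1:1 to the cases on sex, five-year birth cohort and birth-in-state status
(and, where required, presence of a death record).  The empirical
significance is the fraction of control sets whose GIF reaches the case
GIF.

The classical GIF test draws controls from the general (eligible)
population and asks whether cases cluster more than random population
members.  The SubsetGIF test draws the controls from the full case cohort
instead, asking whether a clinically defined *subset* of cases is more
related than cases at large — the sharper question when hunting rare
segregating variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .pedigree import Genealogy, Individual, PairKinship

__all__ = [
    "GIF_SCALE",
    "MatchKey",
    "SubsetDefinition",
    "SUBSET_DEFINITIONS",
    "GIFTestResult",
    "gif_statistic",
    "gif_by_distance",
    "match_key",
    "draw_control_sets",
    "empirical_p",
    "gif_test",
    "subset_gif_test",
    "build_subset",
    "overlap_report",
]

logger = logging.getLogger(__name__)

#: GIF = mean pairwise kinship x GIF_SCALE
GIF_SCALE = 1e5


# -- statistic ------------------------------------------------------------


def gif_statistic(pk: PairKinship, ids: Iterable[str] | None = None) -> float:
    """Scaled mean pairwise kinship over all unordered pairs.

    ``ids`` defaults to the id set the :class:`PairKinship` covers; when
    given it must match.  Requires at least two individuals.
    """
    if ids is not None and frozenset(ids) != pk.ids:
        raise ValueError("ids do not match the PairKinship coverage")
    if len(pk.ids) < 2:
        raise ValueError("GIF requires at least 2 individuals")
    total = sum(phi for _, (phi, _) in pk.nonzero_items())
    return GIF_SCALE * total / pk.n_pairs


def gif_by_distance(
    pk: PairKinship, ids: Iterable[str] | None = None
) -> dict[int, float]:
    """Contribution to the GIF statistic by pairwise genetic distance.

    Entry ``d`` is ``GIF_SCALE * (sum of phi over pairs at distance d) /
    n_pairs``; unreachable pairs contribute to no entry, so the entries sum
    to :func:`gif_statistic`.
    """
    if ids is not None and frozenset(ids) != pk.ids:
        raise ValueError("ids do not match the PairKinship coverage")
    if len(pk.ids) < 2:
        raise ValueError("GIF requires at least 2 individuals")
    sums: dict[int, float] = {}
    for _, (phi, dist) in pk.nonzero_items():
        if dist is not None:
            sums[dist] = sums.get(dist, 0.0) + phi
    return {d: GIF_SCALE * s / pk.n_pairs for d, s in sorted(sums.items())}


# -- matching -------------------------------------------------------------


@dataclass(frozen=True, order=True)
class MatchKey:
    """Control-matching stratum: sex, five-year birth cohort (the bin label
    is ``floor(birth_year / 5) * 5``), birth-in-state flag and whether a
    death record is required."""

    sex: str
    birth_cohort: int
    birth_in_state: bool
    requires_death_record: bool = False


def match_key(ind: Individual, need_death_record: bool = False) -> MatchKey | None:
    """Matching key for one individual, or ``None`` when a matching variable
    (birth year, sex, birth-in-state) is missing — the exclusion signal."""
    if ind.birth_year is None or ind.birth_in_state is None or ind.sex == "unknown":
        return None
    return MatchKey(
        sex=ind.sex,
        birth_cohort=(ind.birth_year // 5) * 5,
        birth_in_state=ind.birth_in_state,
        requires_death_record=need_death_record,
    )


def _pool_index(
    g: Genealogy, pool: Iterable[str], need_death_record: bool
) -> dict[MatchKey, list[str]]:
    index: dict[MatchKey, list[str]] = {}
    n_excluded = 0
    for i in sorted(pool):
        ind = g[i]
        if need_death_record and not ind.has_death_record:
            continue
        key = match_key(ind, need_death_record)
        if key is None:
            n_excluded += 1
            continue
        index.setdefault(key, []).append(i)
    if n_excluded:
        logger.info("excluded %d pool members missing matching variables", n_excluded)
    return index


def draw_control_sets(
    g: Genealogy,
    cases: Iterable[str],
    pool: Iterable[str],
    R: int,
    seed: int,
    *,
    need_death_record: bool = False,
    exclude_cases: bool = False,
) -> list[list[str]]:
    """Draw ``R`` matched control sets, one control per case.

    Within each replicate controls are drawn without replacement and each
    control carries the same :class:`MatchKey` as the case it replaces.
    When a stratum runs short the birth cohort is widened stepwise by ±5
    years (logged); exhausting the whole (sex, birth-state) margin raises a
    hard error naming the stratum.  By default the pool may contain the
    cases themselves (the null treats the case set as a random matched
    draw); set ``exclude_cases`` to remove them.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    cases = sorted(set(cases))
    pool = set(pool)
    if exclude_cases:
        pool -= set(cases)
    index = _pool_index(g, pool, need_death_record)
    counts: dict[MatchKey, int] = {}
    for c in cases:
        key = match_key(g[c], need_death_record)
        if key is None:
            raise ValueError(f"case {c!r} is missing a matching variable")
        counts[key] = counts.get(key, 0) + 1
    # per (sex, state) margin: sorted cohorts available, for widening
    cohorts_by_margin: dict[tuple[str, bool], list[int]] = {}
    for key in index:
        cohorts_by_margin.setdefault(
            (key.sex, key.birth_in_state), []
        ).append(key.birth_cohort)
    for v in cohorts_by_margin.values():
        v.sort()

    def candidates(key: MatchKey, width: int) -> list[str]:
        out: list[str] = []
        for cohort in range(key.birth_cohort - width, key.birth_cohort + width + 5, 5):
            out.extend(
                index.get(
                    MatchKey(key.sex, cohort, key.birth_in_state, key.requires_death_record),
                    (),
                )
            )
        return out

    max_width: dict[MatchKey, int] = {}
    for key in counts:
        margin = cohorts_by_margin.get((key.sex, key.birth_in_state), [])
        if not margin:
            raise ValueError(f"no controls at all for stratum {key}")
        max_width[key] = max(
            abs(margin[0] - key.birth_cohort), abs(margin[-1] - key.birth_cohort)
        )

    rng = np.random.default_rng(seed)
    widened: set[MatchKey] = set()
    sets: list[list[str]] = []
    strata = sorted(counts.items())
    for _ in range(R):
        used: set[str] = set()
        chosen: list[str] = []
        for key, n_needed in strata:
            width = 0
            cand = [c for c in candidates(key, width) if c not in used]
            while len(cand) < n_needed and width < max_width[key]:
                width += 5
                cand = [c for c in candidates(key, width) if c not in used]
            if len(cand) < n_needed:
                raise ValueError(
                    f"stratum {key} exhausted: {n_needed} controls needed, "
                    f"{len(cand)} available after maximal cohort widening"
                )
            if width and key not in widened:
                widened.add(key)
                logger.info(
                    "stratum %s widened by ±%d years to find %d controls",
                    key, width, n_needed,
                )
            picks = rng.choice(len(cand), size=n_needed, replace=False)
            for p in picks:
                chosen.append(cand[p])
                used.add(cand[p])
        sets.append(chosen)
    return sets


# -- empirical significance ------------------------------------------------


def empirical_p(case_gif: float, control_gifs: Sequence[float]) -> tuple[float, bool]:
    """Empirical significance of the case GIF against control replicates.

    Returns ``(p, below_resolution)`` with ``p`` the fraction of control
    GIFs greater than or equal to the case GIF (ties count as exceedances —
    conservative).  When no control reaches the case GIF the test is below
    its Monte Carlo resolution and should be displayed as ``< 1/R``.
    """
    control_gifs = np.asarray(control_gifs, dtype=float)
    R = control_gifs.size
    if R < 1:
        raise ValueError("at least one control replicate required")
    count = int(np.sum(control_gifs >= case_gif))
    return count / R, count == 0


def format_p(p: float, below_resolution: bool, R: int) -> str:
    """Table-style display: ``<1/R`` when below resolution, else 3 decimals."""
    if below_resolution:
        return f"<{1.0 / R:g}"
    return f"{p:.3f}"


# -- test results ----------------------------------------------------------


@dataclass
class GIFTestResult:
    """One GIF or SubsetGIF test: observed statistic, control distribution,
    empirical significance and the per-genetic-distance decomposition."""

    n_cases: int
    case_gif: float
    control_gifs: np.ndarray
    empirical_p: float
    below_resolution: bool
    by_distance: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def mean_control_gif(self) -> float:
        return float(np.mean(self.control_gifs))

    @property
    def R(self) -> int:
        return int(self.control_gifs.size)

    @property
    def p_display(self) -> str:
        return format_p(self.empirical_p, self.below_resolution, self.R)


def _control_by_distance_mean(
    per_replicate: list[dict[int, float]]
) -> dict[int, float]:
    sums: dict[int, float] = {}
    for contrib in per_replicate:
        for d, v in contrib.items():
            sums[d] = sums.get(d, 0.0) + v
    return {d: s / len(per_replicate) for d, s in sums.items()}


def gif_test(
    g: Genealogy,
    cases: Iterable[str],
    population_pool: Iterable[str],
    R: int = 1000,
    seed: int = 0,
    *,
    need_death_record: bool = False,
    exclude_cases: bool = False,
) -> GIFTestResult:
    """Classical GIF test: do the cases cluster more than matched draws from
    the population pool?"""
    cases = sorted(set(cases))
    if len(cases) < 2:
        raise ValueError("GIF test requires at least 2 cases")
    pk = g.all_pairs_kinship(cases)
    case_gif = gif_statistic(pk)
    case_by_d = gif_by_distance(pk)
    control_sets = draw_control_sets(
        g, cases, population_pool, R, seed,
        need_death_record=need_death_record, exclude_cases=exclude_cases,
    )
    control_gifs = np.empty(R)
    control_by_d: list[dict[int, float]] = []
    for r, ids in enumerate(control_sets):
        cpk = g.all_pairs_kinship(ids)
        control_gifs[r] = gif_statistic(cpk)
        control_by_d.append(gif_by_distance(cpk))
    p, below = empirical_p(case_gif, control_gifs)
    mean_by_d = _control_by_distance_mean(control_by_d)
    by_distance = {
        d: (case_by_d.get(d, 0.0), mean_by_d.get(d, 0.0))
        for d in sorted(set(case_by_d) | set(mean_by_d))
    }
    return GIFTestResult(
        n_cases=len(cases),
        case_gif=case_gif,
        control_gifs=control_gifs,
        empirical_p=p,
        below_resolution=below,
        by_distance=by_distance,
    )


def subset_gif_test(
    g: Genealogy,
    subset: Iterable[str],
    all_cases: Iterable[str],
    R: int = 1000,
    seed: int = 0,
    *,
    need_death_record: bool = False,
    exclude_subset: bool = False,
) -> GIFTestResult:
    """SubsetGIF test: is a clinical subset of cases more related than the
    case cohort at large?

    Identical machinery to :func:`gif_test` with the control pool replaced
    by the full case cohort (restricted to death-record cases when
    ``need_death_record`` is set).  The case GIF of the subset is unchanged
    from its classical-test value — the same pairs are averaged — only the
    control distribution moves.
    """
    subset = set(subset)
    all_cases = set(all_cases)
    if not subset <= all_cases:
        raise ValueError("subset must be contained in the case cohort")
    return gif_test(
        g, subset, all_cases, R, seed,
        need_death_record=need_death_record, exclude_cases=exclude_subset,
    )


# -- clinical subsets ------------------------------------------------------


@dataclass(frozen=True)
class SubsetDefinition:
    """A named, phenotype-defined subset of the case cohort plus the control
    pool its SubsetGIF test requires."""

    name: str
    predicate: Callable[[Individual], bool]
    control_pool_rule: str = "all_cases"  # population | all_cases | death_certificate_cases
    description: str = ""


def _attr(ind: Individual, key: str):
    return ind.attributes.get(key)


def _num(ind: Individual, key: str) -> float | None:
    v = ind.attributes.get(key)
    return None if v is None else float(v)


def _early_onset(ind: Individual) -> bool:
    v = _num(ind, "age_at_diagnosis")
    return v is not None and v < 50


def _other_primary(ind: Individual) -> bool:
    v = _num(ind, "other_primary_count")
    return v is not None and v >= 1


def _gleason_gt7(ind: Individual) -> bool:
    v = _num(ind, "gleason")
    return v is not None and v > 7


def _short_survival(ind: Individual) -> bool:
    v = _num(ind, "survival_months")
    return v is not None and 0 <= v <= 9


def _long_survival(ind: Individual) -> bool:
    v = _num(ind, "survival_months")
    return v is not None and v >= 240


def _high_bmi(ind: Individual) -> bool:
    v = _num(ind, "bmi")
    return v is not None and v >= 30


_SUBSET_LIST = [
    SubsetDefinition("all", lambda ind: True, "population", "All cases"),
    SubsetDefinition("early_onset", _early_onset,
                     description="Age at diagnosis <50 years"),
    SubsetDefinition("metastatic_at_dx",
                     lambda ind: _attr(ind, "metastatic") is True,
                     description="Metastatic disease at diagnosis"),
    SubsetDefinition("other_primary", _other_primary,
                     description="At least 1 primary cancer of other site"),
    SubsetDefinition("gleason_gt7", _gleason_gt7,
                     description="Gleason score >7 at diagnosis"),
    SubsetDefinition("short_survival", _short_survival,
                     description="Short survival (0-9 months)"),
    SubsetDefinition("long_survival", _long_survival,
                     description="Long survival (240+ months)"),
    SubsetDefinition("high_bmi", _high_bmi, description="High BMI (>=30)"),
    SubsetDefinition("lethal",
                     lambda ind: _attr(ind, "cause_of_death_phenotype") is True,
                     "death_certificate_cases",
                     "Phenotype as cause of death (lethal)"),
]

SUBSET_DEFINITIONS: dict[str, SubsetDefinition] = {d.name: d for d in _SUBSET_LIST}


def build_subset(
    cases: Iterable[Individual], definition: SubsetDefinition | str
) -> set[str]:
    """Ids of the cases satisfying a subset predicate.

    A missing attribute excludes the case (no imputation), mirroring how
    incomplete BMI and death-certificate coverage is handled in registry
    data.
    """
    if isinstance(definition, str):
        try:
            definition = SUBSET_DEFINITIONS[definition]
        except KeyError:
            raise ValueError(f"unknown subset name {definition!r}") from None
    return {ind.id for ind in cases if definition.predicate(ind)}


def overlap_report(subsets: Mapping[str, set[str]]) -> "pd.DataFrame":
    """Pairwise overlap counts and percentages between named subsets.

    For each ordered pair the percentage is the overlap count over the
    second subset's size (the denominator set), rounded to one decimal —
    e.g. an overlap of 2459 within a denominator of 11536 reports 21.3%.
    """
    import pandas as pd

    rows = []
    names = sorted(subsets)
    for a in names:
        for b in names:
            if a == b:
                continue
            n_overlap = len(subsets[a] & subsets[b])
            denom = len(subsets[b])
            rows.append(
                {
                    "subset": a,
                    "denominator": b,
                    "n_overlap": n_overlap,
                    "n_denominator": denom,
                    "percent": round(100.0 * n_overlap / denom, 1) if denom else float("nan"),
                }
            )
    return pd.DataFrame(rows)
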