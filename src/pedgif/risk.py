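"""High-risk pedigree identification: observed vs expected case counts.

A founder's descendant set is a pedigree; it is *high risk* when it holds
significantly more phenotype cases than expected from sex- and birth-cohort-
specific rates in the reference population.  The expectation for each
descendant is their stratum's case rate, summed over the pedigree; the
excess probability is the one-sided upper Poisson tail at that summed mean.

Rates are person-based (each eligible person contributes once, not
person-years) and are computed internally from the analysed population, so
no external incidence table is needed.  p-values are reported raw; no
correction is applied across founders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .pedigree import Genealogy, Individual

__all__ = [
    "RateTable",
    "PedigreeExcessResult",
    "cohort_rates",
    "expected_cases",
    "excess_p",
    "pedigree_excess_scan",
]


@dataclass(frozen=True)
class RateTable:
    """Case rates by (sex, five-year birth cohort) stratum.

    Strata with no eligible persons carry no rate; looking one up yields 0.
    """

    rates: dict[tuple[str, int], float]

    def rate_for(self, ind: Individual) -> float:
        if ind.birth_year is None:
            return 0.0
        return self.rates.get((ind.sex, (ind.birth_year // 5) * 5), 0.0)


@dataclass(frozen=True)
class PedigreeExcessResult:
    founder_id: str
    n_descendants: int
    observed: int
    expected: float
    p: float


def cohort_rates(
    population: Iterable[Individual], cases: Iterable[str]
) -> RateTable:
    """Stratum case rate = cases in stratum / persons in stratum, over
    (sex, five-year birth cohort)."""
    cases = set(cases)
    n: dict[tuple[str, int], int] = {}
    k: dict[tuple[str, int], int] = {}
    for ind in population:
        if ind.birth_year is None:
            continue
        key = (ind.sex, (ind.birth_year // 5) * 5)
        n[key] = n.get(key, 0) + 1
        if ind.id in cases:
            k[key] = k.get(key, 0) + 1
    if not n:
        raise ValueError("population has no individuals with a birth year")
    return RateTable({key: k.get(key, 0) / n[key] for key in n})


def expected_cases(
    g: Genealogy, founder: str, rates: RateTable, eligible: Iterable[str]
) -> tuple[set[str], float]:
    """Descendant set of a founder (restricted to the eligible ids) and the
    expected case count among them under the stratum rates."""
    eligible = set(eligible)
    desc = g.descendants(founder) & eligible
    expected = sum(rates.rate_for(g[i]) for i in desc)
    return desc, expected


def excess_p(observed: int, expected: float) -> float:
    """One-sided upper-tail Poisson probability P(X >= observed | mean =
    expected).  Observed 0 always yields 1."""
    if observed < 0:
        raise ValueError("observed count must be nonnegative")
    if observed == 0:
        return 1.0
    if expected <= 0:
        raise ValueError("expected must be positive when cases are observed")
    return float(stats.poisson.sf(observed - 1, expected))


def pedigree_excess_scan(
    g: Genealogy,
    cases: Iterable[str],
    eligible: Iterable[str],
    founders: Iterable[str] | None = None,
    min_descendants: int = 2,
) -> pd.DataFrame:
    """Observed/expected/p for every founder's descendant pedigree.

    Rates come from the eligible population itself.  Returns a DataFrame
    sorted by ascending p (founders with fewer than ``min_descendants``
    eligible descendants are dropped).
    """
    cases = set(cases)
    eligible = set(eligible)
    rates = cohort_rates((g[i] for i in sorted(eligible)), cases)
    rows = []
    for f in sorted(founders) if founders is not None else sorted(g.founders):
        desc, expected = expected_cases(g, f, rates, eligible)
        if len(desc) < min_descendants:
            continue
        observed = len(desc & cases)
        p = excess_p(observed, expected) if expected > 0 else 1.0
        rows.append(
            PedigreeExcessResult(
                founder_id=f,
                n_descendants=len(desc),
                observed=observed,
                expected=expected,
                p=p,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if not df.empty:
        df = df.sort_values(["p", "founder_id"], ignore_index=True)
    return df
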