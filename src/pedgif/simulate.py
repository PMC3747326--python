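"""Synthetic multigeneration genealogies with clustered phenotypes.

The generator emulates the shape of a founder-population genealogy
resource: a wave of founder couples, several generations of within-
population marriage with a trickle of immigrant spouses (new founders),
sex and birth-year structure, and partial death-record coverage.  A binary
phenotype is laid on top by dropping a rare dominant variant from founders
through Mendelian inheritance and drawing case status from carrier-
dependent penetrances; clinical sub-attributes (diagnosis age, BMI,
Gleason, metastasis, survival, cause of death) are drawn from simple
parametric models with carrier-dependent enrichment of early onset and
lethality.  Setting the two penetrances equal (and the two lethal
fractions equal) gives an exact null in which case status is independent
of the pedigree.

The module also provides the gene-dropping Monte Carlo kinship oracle used
to validate the exact kinship recursion.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .pedigree import FEMALE, MALE, Genealogy, Individual, write_pedigree

__all__ = [
    "SimulationConfig",
    "null_config",
    "power_config",
    "simulate_genealogy",
    "assign_phenotypes",
    "gene_drop",
    "kinship_mc_oracle",
    "write_simulation",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a modest founder population: 30 founder couples born
    around 1880, five generations separated by 20 ± 3 years, Poisson(3.0)
    offspring per couple, 85% of adults marrying with a 20% immigrant-spouse
    rate, and spouse pairs restricted to kinship ≤ 1/16 (first cousins or
    more distant).  The phenotype is male-restricted with a non-carrier
    lifetime risk of 0.12 and a dominant variant (founder allele frequency
    0.03) raising penetrance to 0.6 and the lethal fraction from 0.15 to
    0.55.
    """

    n_founder_couples: int = 30
    n_generations: int = 5
    offspring_mean: float = 3.0
    marriage_rate: float = 0.85
    immigrant_spouse_rate: float = 0.2
    max_spouse_kinship: float = 1.0 / 16.0
    founder_birth_year: int = 1880
    generation_gap_mean: float = 20.0
    generation_gap_sd: float = 3.0
    sex_ratio: float = 0.5
    death_record_rate: float = 0.85

    variant_founder_freq: float = 0.03
    penetrance_carrier: float = 0.6
    penetrance_noncarrier: float = 0.12

    # clinical attribute model (cases only)
    dx_age_mean: float = 70.0
    dx_age_sd: float = 9.0
    dx_age_carrier_shift: float = -8.0
    bmi_mean: float = 27.5
    bmi_sd: float = 4.8
    bmi_missing_rate: float = 0.35
    gleason_levels: tuple = (6, 7, 8, 9)
    gleason_probs: tuple = (0.30, 0.35, 0.22, 0.13)
    metastatic_rate: float = 0.08
    other_primary_mean: float = 0.15
    lethal_prob_carrier: float = 0.55
    lethal_prob_noncarrier: float = 0.15
    survival_lethal_logmean: float = 3.4
    survival_lethal_logsd: float = 0.9
    survival_nonlethal_logmean: float = 4.9
    survival_nonlethal_logsd: float = 0.7

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 2:
            raise ValueError("n_generations must be >= 2")
        for name in (
            "marriage_rate", "immigrant_spouse_rate", "sex_ratio",
            "death_record_rate", "variant_founder_freq",
            "penetrance_carrier", "penetrance_noncarrier",
            "lethal_prob_carrier", "lethal_prob_noncarrier",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.offspring_mean <= 0:
            raise ValueError("offspring_mean must be positive")
        if not math.isclose(sum(self.gleason_probs), 1.0, abs_tol=1e-9):
            raise ValueError("gleason_probs must sum to 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gleason_levels"] = list(self.gleason_levels)
        d["gleason_probs"] = list(self.gleason_probs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for k in ("gleason_levels", "gleason_probs"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def null_config(**overrides) -> SimulationConfig:
    """Conditions with case status independent of the pedigree: both
    penetrances at the non-carrier rate and no lethal enrichment."""
    cfg = SimulationConfig(
        penetrance_carrier=0.12,
        penetrance_noncarrier=0.12,
        lethal_prob_carrier=0.15,
        lethal_prob_noncarrier=0.15,
        dx_age_carrier_shift=0.0,
    )
    return cfg.replace(**overrides)


def power_config(**overrides) -> SimulationConfig:
    """Strong-signal alternative used for power evaluation.

    Emulates a rare segregating variant that moderately raises disease risk
    (penetrance 0.5 vs 0.12) but strongly drives lethality (0.9 vs 0.05),
    so carriers concentrate in the lethal subset rather than in the case
    cohort at large — the situation the SubsetGIF test is designed to
    detect.  The genealogy is deeper and wider than the default (50 founder
    couples, six generations from 1870, 15% immigrant spouses) so carrier
    lineages grow large enough for the subset to hold ~25 members.
    """
    cfg = SimulationConfig(
        n_founder_couples=50,
        n_generations=6,
        founder_birth_year=1870,
        generation_gap_mean=18.0,
        immigrant_spouse_rate=0.15,
        variant_founder_freq=0.05,
        penetrance_carrier=0.5,
        penetrance_noncarrier=0.12,
        lethal_prob_carrier=0.9,
        lethal_prob_noncarrier=0.05,
    )
    return cfg.replace(**overrides)


# -- genealogy construction ------------------------------------------------


class _Builder:
    """Incremental pedigree state with a local kinship memo, so the spouse
    constraint (kinship ≤ max_spouse_kinship) can be checked while the
    genealogy is still under construction."""

    def __init__(self) -> None:
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        self._memo: dict[tuple[str, str], float] = {}
        self._depth: dict[str, int] = {}

    def add(self, i: str, father: str | None, mother: str | None) -> None:
        self.parents[i] = (father, mother)
        d = 0
        for p in (father, mother):
            if p is not None:
                d = max(d, self._depth[p] + 1)
        self._depth[i] = d

    def kinship(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        phi = self._memo.get(key)
        if phi is not None:
            return phi
        if a == b:
            f, m = self.parents[a]
            phi = 0.5 * (1.0 + (self.kinship(f, m) if f and m else 0.0))
        else:
            if self._depth[a] < self._depth[b]:
                a, b = b, a
            f, m = self.parents[a]
            phi = 0.5 * (
                (self.kinship(f, b) if f else 0.0)
                + (self.kinship(m, b) if m else 0.0)
            )
        self._memo[key] = phi
        return phi


def simulate_genealogy(cfg: SimulationConfig) -> Genealogy:
    """Build one synthetic genealogy; deterministic given ``cfg.seed``.

    Founder couples seed generation 0; each couple bears Poisson-distributed
    children, who marry within their generation subject to the kinship cap,
    or to immigrant spouses (new founders carrying no prior relatedness).
    Birth-in-state is False for founders and immigrants, True for the
    native-born; death records are assigned at ``death_record_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    builder = _Builder()
    individuals: list[Individual] = []
    serial = 0

    def new_person(
        sex: str,
        birth_year: int,
        father: str | None,
        mother: str | None,
        in_state: bool,
    ) -> Individual:
        nonlocal serial
        serial += 1
        ind = Individual(
            id=f"I{serial:05d}",
            father_id=father,
            mother_id=mother,
            sex=sex,
            birth_year=int(birth_year),
            birth_in_state=in_state,
            has_death_record=bool(rng.random() < cfg.death_record_rate),
        )
        individuals.append(ind)
        builder.add(ind.id, father, mother)
        return ind

    def immigrant(sex: str, birth_year: float) -> Individual:
        year = rng.normal(birth_year, cfg.generation_gap_sd / 2)
        return new_person(sex, round(year), None, None, in_state=False)

    couples: list[tuple[Individual, Individual]] = []
    for _ in range(cfg.n_founder_couples):
        year = rng.normal(cfg.founder_birth_year, cfg.generation_gap_sd)
        husband = new_person(MALE, round(rng.normal(year, 2)), None, None, False)
        wife = new_person(FEMALE, round(rng.normal(year, 2)), None, None, False)
        couples.append((husband, wife))

    for gen in range(1, cfg.n_generations):
        children: list[Individual] = []
        for husband, wife in couples:
            n_kids = rng.poisson(cfg.offspring_mean)
            mid_parent = 0.5 * (husband.birth_year + wife.birth_year)
            for _ in range(n_kids):
                sex = MALE if rng.random() < cfg.sex_ratio else FEMALE
                year = rng.normal(
                    mid_parent + cfg.generation_gap_mean, cfg.generation_gap_sd
                )
                children.append(
                    new_person(sex, round(year), husband.id, wife.id, True)
                )
        if gen == cfg.n_generations - 1:
            couples = []
            break
        marrying = [c for c in children if rng.random() < cfg.marriage_rate]
        males = [c for c in marrying if c.sex == MALE]
        females = [c for c in marrying if c.sex == FEMALE]
        couples = []
        for groom in males:
            if females and rng.random() >= cfg.immigrant_spouse_rate:
                match = None
                for idx, bride in enumerate(females):
                    if builder.kinship(groom.id, bride.id) <= cfg.max_spouse_kinship:
                        match = idx
                        break
                if match is not None:
                    couples.append((groom, females.pop(match)))
                    continue
            couples.append((groom, immigrant(FEMALE, groom.birth_year)))
        for bride in females:
            couples.append((immigrant(MALE, bride.birth_year), bride))
    return Genealogy(individuals)


# -- phenotype model -------------------------------------------------------


def gene_drop(
    g: Genealogy, rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    """One Mendelian transmission of founder alleles down the pedigree.

    Each founder carries two globally unique integer labels; every
    non-founder allele is a uniform random pick from the corresponding
    parent's pair, so any label seen anywhere traces back to a founder.
    """
    alleles: dict[str, tuple[int, int]] = {}
    next_label = 0
    for i in g.topological_order():
        ind = g[i]
        pair = []
        for p in (ind.father_id, ind.mother_id):
            if p is None:
                pair.append(next_label)
                next_label += 1
            else:
                pair.append(alleles[p][rng.integers(0, 2)])
        alleles[i] = (pair[0], pair[1])
    return alleles


def assign_phenotypes(
    g: Genealogy, cfg: SimulationConfig, seed: int | None = None
) -> dict[str, bool]:
    """Assign case status and clinical attributes in place; returns the
    carrier truth map (id -> carries at least one variant allele).

    A dominant variant is dropped from founders at the configured allele
    frequency; males become cases with carrier-dependent penetrance.  Cases
    receive diagnosis age (carrier-shifted), BMI (missing at the configured
    rate), Gleason score, metastasis flag, other-primary count, lethality
    (carrier-enriched; lethal cases always gain a death record and shorter
    survival) and survival months.  Cause-of-death status is only recorded
    for cases with a death record, mirroring incomplete certificate
    linkage.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    order = g.topological_order()
    variant: dict[str, tuple[int, int]] = {}
    for i in order:
        ind = g[i]
        pair = []
        for p in (ind.father_id, ind.mother_id):
            if p is None:
                pair.append(int(rng.random() < cfg.variant_founder_freq))
            else:
                pair.append(variant[p][rng.integers(0, 2)])
        variant[i] = (pair[0], pair[1])
    carriers = {i: bool(variant[i][0] or variant[i][1]) for i in order}

    for i in order:
        ind = g[i]
        carrier = carriers[i]
        penetrance = (
            cfg.penetrance_carrier if carrier else cfg.penetrance_noncarrier
        )
        is_case = ind.sex == MALE and rng.random() < penetrance
        ind.attributes["is_case"] = is_case
        if not is_case:
            continue
        shift = cfg.dx_age_carrier_shift if carrier else 0.0
        dx_age = max(35.0, rng.normal(cfg.dx_age_mean + shift, cfg.dx_age_sd))
        ind.attributes["age_at_diagnosis"] = int(round(dx_age))
        if rng.random() >= cfg.bmi_missing_rate:
            ind.attributes["bmi"] = round(
                max(15.0, rng.normal(cfg.bmi_mean, cfg.bmi_sd)), 1
            )
        ind.attributes["gleason"] = int(
            rng.choice(cfg.gleason_levels, p=cfg.gleason_probs)
        )
        ind.attributes["metastatic"] = bool(rng.random() < cfg.metastatic_rate)
        ind.attributes["other_primary_count"] = int(
            rng.poisson(cfg.other_primary_mean)
        )
        p_lethal = cfg.lethal_prob_carrier if carrier else cfg.lethal_prob_noncarrier
        lethal = bool(rng.random() < p_lethal)
        if lethal:
            ind.has_death_record = True
            ind.attributes["cause_of_death_phenotype"] = True
            ind.attributes["survival_months"] = int(
                round(rng.lognormal(cfg.survival_lethal_logmean,
                                    cfg.survival_lethal_logsd))
            )
        else:
            if ind.has_death_record:
                ind.attributes["cause_of_death_phenotype"] = False
            ind.attributes["survival_months"] = int(
                round(rng.lognormal(cfg.survival_nonlethal_logmean,
                                    cfg.survival_nonlethal_logsd))
            )
    return carriers


# -- gene-dropping kinship oracle ------------------------------------------


def kinship_mc_oracle(
    g: Genealogy, a: str, b: str, reps: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte Carlo estimate of the kinship coefficient by gene dropping.

    Over ``reps`` independent drops of founder-unique alleles, the
    per-replicate statistic is the fraction of the four allele pairings
    between ``a`` and ``b`` that are identical by descent; its mean
    estimates phi(a, b).  Returns ``(estimate, standard error)``.
    Vectorised over replicates, so 10**5 drops on a small pedigree take a
    fraction of a second.
    """
    g[a], g[b]
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    next_label = 0
    for i in g.topological_order():
        ind = g[i]
        pair = []
        for p in (ind.father_id, ind.mother_id):
            if p is None:
                pair.append(np.full(reps, next_label, dtype=np.int32))
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=reps)
                pa, pb = alleles[p]
                pair.append(np.where(pick == 0, pa, pb))
        alleles[i] = (pair[0], pair[1])
    a1, a2 = alleles[a]
    b1, b2 = alleles[b]
    ibd = (
        (a1 == b1).astype(np.float64)
        + (a1 == b2)
        + (a2 == b1)
        + (a2 == b2)
    ) / 4.0
    estimate = float(ibd.mean())
    se = float(ibd.std(ddof=1) / math.sqrt(reps)) if reps > 1 else float("nan")
    return estimate, se


# -- output ---------------------------------------------------------------


def write_simulation(
    g: Genealogy,
    carriers: Mapping[str, bool],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the pedigree/attribute file pair plus the carrier truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.fam",
        "attributes": outdir / "attributes.csv",
        "truth": outdir / "truth.csv",
    }
    write_pedigree(g, paths["pedigree"], paths["attributes"])
    with open(paths["truth"], "w") as fh:
        fh.write("id,carrier\n")
        for i in g.topological_order():
            fh.write(f"{i},{int(carriers[i])}\n")
    return paths
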