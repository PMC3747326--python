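# Methods

## Kinship and genetic distance

Kinship is the Malécot coefficient `φ(a, b)`, computed by the standard
recursion on the parent-link DAG: `φ(a, a) = (1 + φ(f_a, m_a)) / 2`, and
for distinct individuals `φ(a, b) = (φ(f_a, b) + φ(m_a, b)) / 2` where `a`
is the member of greater generation depth (depth = longest parent chain
above, so the expanded member can never be an ancestor of the other and the
recursion terminates). Missing parents contribute zero; a missing parent is
therefore equivalent to a unique unrelated founder, which is the
conservative reading of incomplete registry genealogy. Inbreeding loops are
handled exactly by the recursion — no approximation is made for pedigrees
where spouses are related.

Results are memoised per unordered pair on the `Genealogy` instance, and a
pair whose ancestor sets are disjoint short-circuits to zero. For set-level
work, `all_pairs_kinship` builds an ancestor→members index so that only
pairs sharing at least one ancestor are evaluated; with sparse relatedness
the cost scales with the number of related pairs, not `n²`.

Genetic distance is the minimum meiosis count over all common ancestors
(including the pair members themselves): `min_c d_a(c) + d_b(c)` over
per-individual ancestor maps that carry minimum meiotic depth. This yields
the conventional scale — 1 parent/offspring, 2 siblings or
grandparent/grandchild, 3 avunculars, 4 first cousins, 5 first cousins once
removed — and `unreachable` for pairs with no common ancestor, which is
exactly the set of pairs with zero kinship.

## The GIF and SubsetGIF tests

`GIF = 10^5 × mean pairwise kinship`. The scale constant is a display
convention of the GIF literature (it puts population-level values near
single digits on very large genealogies); it cancels in every comparison,
so nothing statistical depends on it.

Significance is purely empirical. Controls are matched 1:1 to cases on the
`MatchKey` stratum (sex, five-year birth cohort `floor(year/5)*5`,
birth-in-state flag, and — for death-certificate phenotypes — presence of a
death record), drawn without replacement within each replicate. The
empirical p is `#{r : GIF_control_r ≥ GIF_case} / R`, counting ties as
exceedances (conservative); zero exceedances are displayed as `<1/R`
because the Monte Carlo cannot resolve smaller values. The default is
R = 1000 replicates.

Two design points were genuinely open and are resolved as follows:

- **The control pool includes the cases themselves** (and the subset
  members, for SubsetGIF). The null hypothesis is "the (sub)set is a random
  matched draw from the pool", under which the observed set is one
  exchangeable draw among the R+1; excluding it would bias the control
  distribution low. A switch (`exclude_cases`) is exposed.
- **Stratum exhaustion falls back to cohort widening**: if a stratum cannot
  supply enough controls, the birth cohort is widened by ±5 years stepwise
  (logged) before drawing; only when the whole (sex, birth-state) margin is
  exhausted does the draw fail hard. Matching is exact whenever no widening
  was logged, and the test suite verifies the control MatchKey multiset
  equals the case multiset in every replicate of unwidened runs.

The SubsetGIF test is the same machinery with the control pool replaced by
the full case cohort; for the lethal subset (phenotype as cause of death)
the pool is restricted to cases with a death record, in both the classical
and the subset tests, because certificate linkage itself selects for record
quality. Eligibility for any analysis is the ancestral-completeness filter:
born strictly before the cutoff year (default 1972) with both parents, all
four grandparent slots, and at least six of eight great-grandparent slots
filled. Slots are counted positionally through the parent links, so in an
inbred ancestry one person occupying two slots counts twice.

Clinical subsets follow fixed boundary conventions: early onset is
diagnosis age < 50 (strict), Gleason > 7 (strict), short survival 0–9
months inclusive, long survival ≥ 240 months, high BMI ≥ 30 kg/m²
(inclusive), metastatic and lethal are boolean flags. A case missing the
attribute a predicate needs is excluded from that subset, not imputed.

## High-risk pedigree test

For each founder, the observed case count among eligible descendants is
compared with `E = Σ_d rate(sex_d, cohort_d)`, the sum of sex- and
five-year-cohort-specific case rates computed from the analysed population
itself (person-based, not person-years: each eligible person counts once).
The excess probability is the exact one-sided Poisson tail
`P(X ≥ observed | mean = E)`. The Poisson model treats descendants as
independent given their strata, which ignores the within-pedigree
correlation the GIF test exists to detect; it is the conventional screening
statistic for this design and is reported raw, with no correction across
founders (flag-worthy when scanning many founders).

## Synthetic genealogies

The generator emulates the *shape* of a founder-population genealogy
resource: founder couples (default 30, born ≈1880 ± 3 y), five generations
separated by 20 ± 3 years, Poisson(3.0) offspring per couple, 85% of adults
marrying, 15–20% immigrant spouses entering as new founders, and spouse
pairs constrained to kinship ≤ 1/16 (first cousins or more distant) to
mimic an outbred open population. Birth-in-state is false for founders and
immigrants, true for the native-born; death records are assigned at rate
0.85. These defaults give ~750 individuals of whom ~280 pass the ancestral
filter (~150 males).

The phenotype model is a single dominant variant dropped from founders at
allele frequency 0.03, with male-only case status at penetrance 0.6
(carriers) vs 0.12 (non-carriers ≈ lifetime prostate-type risk), and
carrier-dependent enrichment of early diagnosis (−8 y shift on a 70 ± 9 y
diagnosis age) and lethality (0.55 vs 0.15). BMI is N(27.5, 4.8²) kg/m²
and missing for 35% of cases; Gleason is categorical on {6,7,8,9};
survival is lognormal, shorter for lethal cases; lethal cases always carry
a death record. `null_config()` sets both penetrances to 0.12 and removes
every carrier effect, making case status exactly independent of the
pedigree. `power_config()` is the documented strong-signal alternative: a
variant at founder allele frequency 0.05 with penetrance 0.5 vs 0.12 but
lethal fraction 0.9 vs 0.05, on a deeper genealogy (50 founder couples, six
generations from 1870). That shape — moderate risk elevation, strong
lethality drive — concentrates carriers in the lethal subset rather than in
the case cohort at large, which is the alternative the SubsetGIF test is
built to detect; a variant with near-complete penetrance would enrich all
cases equally and leave the subset contrast empty.

What the generator does **not** emulate: realistic demography (migration
waves, cohort-varying fertility and mortality), age-structured incidence,
assortative mating, polygenic liability, or record-linkage error. Passing
tests therefore show that the statistics behave correctly on genealogies
with this covariance structure, not that any particular real population's
absolute GIF values are recovered — on these small dense cohorts mean
kinship is orders of magnitude higher than in a millions-strong genealogy,
so GIF magnitudes are not comparable to published population values.

## Validation design and problem sizes

- **Oracle agreement**: the kinship recursion is checked against an
  independent gene-dropping Monte Carlo (founder-unique alleles transmitted
  by fair Mendelian choice; the IBD fraction of the four allele pairings
  estimates φ) at 10⁵ replicates on ten random pedigrees spanning at least
  five relationship types, within three standard errors.
- **Conservation**: per-distance contributions sum to the total GIF within
  10⁻⁹ relative, for case sets and every control replicate.
- **Null calibration**: 400 null cohorts (8 genealogies × 50 independent
  phenotype draws) at R = 200; rejection at α ∈ {0.05, 0.10} within three
  binomial standard errors. The SubsetGIF analogue uses 100 random
  half-subsets of null cohorts.
- **Power**: 100 cohorts at `power_config`, lethal subset vs all cases at
  R = 200; rejection at 0.05 in ≥ 80% of runs.
- **Reproducibility**: identical inputs, R and seed give bitwise-identical
  results; CLI runs are compared byte-for-byte against golden files.

These sizes keep the full suite under two minutes on one CPU while leaving
the Monte Carlo resolution (1/200) well below the α levels being checked.

## Numerical notes and edge cases

- Empirical p at R replicates takes values on {0, 1/R, …, 1}; under the
  null its distribution is uniform on that grid up to the +1 discreteness
  of rank statistics, which the calibration bands absorb.
- `gif_statistic` requires ≥ 2 individuals; subsets smaller than that are
  skipped (CLI) or raise (library).
- A pair's distance is `None` exactly when φ = 0; degenerate founder-only
  sets give GIF 0, not an error.
- Control draws, simulation and phenotype assignment each consume a single
  `numpy.random.default_rng(seed)` stream in deterministic iteration
  order; no global RNG state is touched.
- Expected counts of zero with zero observed cases give p = 1; observed
  cases with zero expectation are a domain error rather than p = 0.

## Known limitations

- X-linked and mitochondrial kinship are out of scope; kinship is
  autosomal.
- The matching fallback (cohort widening) slightly relaxes exactness when
  triggered; it is logged but not propagated into the result object.
- The pedigree excess test ignores within-family dependence (see above)
  and multiple testing across founders.
- Absolute GIF values on small synthetic cohorts are not comparable to
  values published for large population genealogies (see scale note).
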