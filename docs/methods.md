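# Methods

## The problem

Two administrative collections record the same births: a midwife-recorded
perinatal collection (here "MDC") covering essentially all births in scope,
and a civil birth registration ("RBDM") covering births whose parents lodged
a registration. Maternal Indigenous status is self-reported to each, and
both under-identify Indigenous mothers — historically about one third are
missed by the midwife collection and one seventh by the registry — while
registration itself is less likely, and more often delayed, for Indigenous
births. The package implements the record-level remedy (a derived status
variable over linked records) together with the aggregate benchmark
(dual-system estimation) used to judge how far the derived variable closes
the gap.

## Derived status

For a linked birth, reported codes (Aboriginal / Torres Strait Islander /
both / neither / not stated) are first collapsed to Indigenous,
non-Indigenous or not-stated; Torres Strait Islander births are too few to
analyse separately. The derived value is Indigenous if either source
collapses to Indigenous; missing only if both are not stated; otherwise
non-Indigenous. Precedence of the "either identifies" rule makes the
derivation symmetric and yields two monotonicity guarantees that the test
suite checks as properties: the derived Indigenous count dominates both
source counts, and the derived missing count is dominated by both sources'
not-stated counts. The derived variable extends to a whole collection by
concatenating linked derived values with the collapsed statuses of that
collection's unlinked records.

## Agreement metrics, not accuracy

With no gold standard, each source is judged against the other on linked
births with both statuses stated: consistency (A+D)/T, relative
sensitivities A/(A+C) and A/(A+B), relative specificities D/(B+D) and
D/(C+D). Relative sensitivity is attenuated relative to true sensitivity
whenever the reference source is itself imperfect; the recovery tests
therefore force one source error-free when checking that the pipeline
returns the configured truth (with both sources imperfect at their default
settings, the measured relative sensitivity of the midwife collection is
~0.52 against a configured true 0.667 — expected behaviour, not a defect).

## Dual-system (capture-recapture) benchmark

Counts n1, n2 (Indigenous-identified per source) and n12 (identified in
both) are taken on linked, both-stated births per year stratum. The Chapman
estimator N̂ = (n1+1)(n2+1)/(n12+1) − 1 is used with its approximate
variance (n1+1)(n2+1)(n1−n12)(n2−n12)/((n12+1)²(n12+2)) and a normal 95% CI
N̂ ± 1.96√Var. Two numerical choices are deliberate:

- **The CI uses the square root of the variance.** Sources sometimes print
  the interval as ±1.96·Var; only the √Var form reproduces the published
  interval that this package's acceptance checks target, and it is the
  standard normal-approximation interval.
- **The point estimate is the Chapman ratio**, not a literal product
  reading of the compactly printed formula; only the ratio reproduces the
  published point estimates.

The CI lower bound is floored at the observed union n1+n2−n12, a logical
bound that matters only in tiny strata. Integer presentation is half-up;
all percentages are half-up to 2 decimals, computed from full-precision
values.

Validity rests on the usual two-list assumptions (closed population,
independence, homogeneous capture, perfect matching). `simulate_two_list`
gives a Monte-Carlo check: at capture probabilities 0.667/0.862 and
N = 5,000 with 2,000 replicates the estimator is unbiased to within
Monte-Carlo error and the CI covers the truth ~95% of the time; with
positively dependent lists (a comonotone-mixture copula preserving the
marginals) the estimate is biased low, illustrating the independence
assumption's failure mode.

A caveat the reporting layer inherits from the assessment it reproduces:
the per-year chi-square comparing the derived-status percentage with the
dual-system percentage treats the estimate as if it were an observed count.
It is not — it carries its own sampling error — so those p-values are
indicative only.

## Proportions and comparisons

Proportion CIs are Wald with z = 1.96, clipped to [0, 100]; this is the
form that reproduces published administrative tables, and at the
denominators in scope (tens of thousands) it is indistinguishable from
better intervals. A Wilson option is available (`method="wilson"`, via
statsmodels) for small strata. Two-proportion comparisons use the Pearson
chi-square without continuity correction (df = 1), appropriate for the
large counts in scope; the test suite cross-checks the statistic against an
independent contingency-table implementation and, for small margins with
expected cell counts ≥ 5, against an exact product-binomial enumeration
(agreement within 0.02 — outside that validity condition the asymptotic
approximation is known to drift further).

## The synthetic generator

`SimConfig` defaults are the study conditions this package emulates:

| parameter | default | meaning |
|---|---|---|
| years | 2001–2005 | cohort years |
| births_per_year | 87,000 | study-scale cohort (~435k births) |
| prevalence | 0.039 | true Indigenous fraction of births |
| sens_mdc / sens_rbdm | 0.667 / 0.862 | P(source reports Indigenous \| Indigenous) |
| spec_mdc / spec_rbdm | 0.9975 / 0.9922 | P(source reports non-Indigenous \| non-Indigenous) |
| miss_mdc / miss_rbdm | 0.0006 / 0.0197 | per-source not-stated rate |
| reg_prob_indig / reg_prob_nonindig | 0.80 / 0.93 | registration probability by status |
| late_reg_extra_loss_final_year | 0.12 | extra registration loss, last cohort year |
| rbdm_only_rate | 0.015 | registrable births outside MDC capture |
| dup_rate_linked / mdc / rbdm | 2.5e-6 / 1e-4 / 1.55e-3 | duplicate re-entry rates |
| id_corruption | 0.02 | per-field identifier noise |
| dependence | 0.0 | shared "hard-to-identify" probability |
| seed | 0 | RNG seed (all streams derive from it) |

Sensitivities, specificities and missingness are anchored to the observed
per-source data quality; the registration probabilities make the
non-registered stratum several-fold Indigenous-enriched; the final-year
loss models registrations delayed past the study window (registration can
lag birth by years, so the last cohort year loses the most);
`rbdm_only_rate` models births registrable but outside the midwife
collection's capture (interstate, under the weight/gestation threshold),
which is what populates the registry-only stratum and gives probabilistic
linkage realistic one-sided records. Duplicate rates reproduce the observed
split of a few hundred duplicates across linked, unlinked-MDC and
unlinked-RBDM strata at study scale. When a source identifies an Indigenous
mother the specific code is drawn 0.95/0.03/0.02 across
Aboriginal/TSI/both, matching the population composition; downstream always
collapses codes.

**Dependence.** Positive correlation between the two sources' identification
of the same mother is modelled by a shared latent "hard-to-identify"
Bernoulli flag: with probability `dependence` neither source identifies an
Indigenous mother, and conditional sensitivities are inflated by
1/(1−dependence) so the marginals are preserved. The inflated sensitivity is
capped at 1, so marginals are exactly preserved only for
dependence ≤ 1 − max(sens); choose dependence accordingly in experiments.

**Identifier noise.** Given/family names are drawn from fixed pools (60/80
names), dates of birth uniformly within the year, postcodes uniformly over
1,000 values. Corruption applies per field at `id_corruption`: a
single-character substitution, or for dates a day/month swap where valid.
This is deliberately minimal — enough to exercise probabilistic linkage,
not a model of real name frequency or typography.

**What passing tests do not show.** The generator draws misclassification
independently across mothers and (at dependence 0) across sources,
identifiers have no family structure (no twins sharing a surname and
address), and true status is binary. Real registries have correlated
reporting within families and communities, time-varying identification
practices, and richer missingness mechanisms; recovery results here
demonstrate that the pipeline's arithmetic is faithful, not that the
derived variable is unbiased on real data.

## Linkage

Oracle mode reproduces a linkage unit's person-level keying from the
generator's hidden person identity, then injects error at per-link rates:
each true link is broken with probability `fn_rate`, and
Binomial(#links, `fp_rate`) false pairs are formed by merging same-year
unlinked groups from opposite sources, each group used at most once. The
per-link reading of the published error rates (0.3% false positive, <0.1%
false negative) is a documented choice; the rates are realized to within
Monte-Carlo error at desk scale.

Weight mode is a self-contained Fellegi–Sunter linker: per-field m/u
probabilities give log2 agreement/disagreement weights (missing fields are
neutral, contributing 0), candidate pairs are blocked by year of birth, and
assignment is greedy one-to-one in descending weight with lexicographic
record-id tie-breaks — deterministic, adequate at desk scale, and
deliberately simpler than production linkage software (no clerical review,
no multi-pass blocking). The default threshold (12 bits) requires agreement
on at least three informative fields. On clean deduplicated input the
weight linker reproduces the oracle exactly; at the default 2% identifier
corruption its sensitivity exceeds 0.98.

## Filters and strata

Duplicates are same-(person, source) re-entries; the first record by id is
kept and exclusions are reported per stratum. Linked births with status not
stated in both sources are excluded from analysis but retained for
denominator accounting (their count is the derived variable's missing
count). Strata: registered-linked (in both collections), registered
registry-only, and non-registered (midwife record with no registration).
Linked births are dated by their MDC year; unlinked records by their own
year of birth, not year of registration. All filters are idempotent and
entity counts reconcile exactly (tested).

## Problem sizes used by the test and acceptance suites

Statistical tests run at desk scale, chosen so each check's discriminating
power is adequate while the whole suite stays fast: conditional-independence
checks at 15,000 births × 20 seeds; parameter recovery at 3 years × 8,000
births × 20 seeds (exact binomial CIs, ≥18/20 containment); source-ordering
checks at 3 years × 6,000 births × 20 seeds; Chapman Monte-Carlo at
N = 5,000 with 2,000 replicates; the exhaustive union bound over all count
triples ≤ 30. Recovery runs use error-free linkage so the measured
quantity is the configured misclassification channel rather than a mixture
with linkage noise; linkage error rates are validated separately.

## Known limitations

- Relative (not true) sensitivity/specificity; no external validation is
  possible by design.
- The dual-system benchmark inherits false-positive identifications: with
  imperfect specificity in both sources, n1·n2 grows faster than n12 and
  the estimate overshoots the true count even as the qualitative ordering
  (MDC < RBDM < derived ≤ estimate) is preserved.
- Mother-level reconciliation across multiple births, and linkage to
  further collections, are out of scope.
- The weight linker is O(pairs-within-year-block) and intended for desk
  scale, not population scale.
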