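# Methods

## Cohort derivation

A participant record carries demographics (sex, age, education), the
regular-exercise answer, height (m), weight (kg) and a set of raw
chronic-condition codes. Processing:

1. **Eligibility.** Age strictly over 45 is read as integer age ≥ 46
   (the youngest reported band is 46–55). Records missing age, exercise,
   anthropometrics or condition data are dropped listwise and logged;
   dropping is never fatal.
2. **Grouping.** The 30 raw condition codes map onto 14 grouped diseases
   via a packaged YAML map (`mmrules/data/grouping_map.yaml`); the map is
   total, surjective, and idempotent on already-grouped codes, so
   pre-grouped input files pass through unchanged. Grouping never
   increases the number of conditions.
3. **Obesity.** BMI = weight / height² with obesity defined as BMI
   strictly greater than 28 kg/m², giving the 15th condition. Files
   recording height in centimeters declare it in the column map and are
   converted on read.
4. **MCD flag.** Multimorbidity = at least two conditions. By default
   all 15 conditions count (obesity included); a switch
   (`mcd_includes_obesity=False`, CLI `--mcd-14-only`) restricts the
   count to the 14 grouped diseases, since summary tables in this
   literature are ambiguous about whether obesity counts.
5. **Stratification.** Any affirmative regular-exercise answer
   (including walking) puts a participant in the active group (AG);
   everyone else is inactive (IG). The strata partition the cohort.

## Mining

Apriori is implemented from scratch (it is the analytical core, not a
commodity step here): level-wise candidate generation by prefix join of
sorted frequent k-itemsets, downward-closure pruning (a candidate dies
if any k-subset is infrequent), and support counting by intersection of
vertical transaction-id sets. Rules take every frequent itemset of size
≥ 2 and every single-item consequent; multi-item consequents are out of
scope (no published rule has one).

Numerical discipline: all threshold comparisons are made on exact
rationals over the integer counts (`Fraction(100 * count, n)`), so a
rule at exactly 1.5% support is kept, a rule at lift exactly 1.5 is
rejected (lift is a strict >, support and confidence are inclusive ≥),
and no floating-point jitter can flip a boundary case. Reported metrics
are rounded to two decimals only at the output layer.

The support threshold applies to the rule's **joint** support by
default. Rule-mining dialects differ — some tools threshold the
antecedent support instead — so `MiningConfig(support_on="antecedent")`
selects that behaviour; in this mode itemsets are enumerated down to the
joint-support floor `min_support × min_confidence / 100`, the smallest
joint support a qualifying rule can have, so thresholding P(A) loses no
rules to pruning.

Output order is deterministic: rules sort by consequent, then
antecedent, matching how published rule tables group by consequent.

An exhaustive `brute_force_rules` enumerator (all itemsets, no pruning,
same threshold arithmetic, refuses > 18 items) serves as the independent
oracle in tests: the Apriori path must equal it exactly on random
instances.

## Post-processing and comparison

A symmetric pair of two-variable rules (A → B, B → A) always co-occurs
and adds no predictive power, so only the higher-confidence member is
kept. Confidence ties (which arise exactly when P(A) = P(B)) are broken
by keeping the lexicographically smaller consequent, making deduplication
idempotent and invariant to input order. The rule is applied at order 2
only: published tables demonstrably retain both members of order-3
symmetric pairs, so higher orders pass through.

Rule sets are compared by **signature** — canonical antecedent set plus
consequent, metrics ignored — into shared and stratum-exclusive parts.
Per-disease appearance counts are naive per-rule-row counts: a disease's
consequent count is the number of rules with it on the right, its
antecedent count the number of rules containing it on the left. The
frequency-increase statistic is 100·(B−A)/A rounded to the nearest
integer, undefined (blank) when the baseline A is zero.

Known discrepancy: for the published tables, naive recounting reproduces
the published per-disease counts for the inactive stratum and for
hypertension and cardiovascular disease in the active stratum, but the
published active-stratum antecedent counts for diabetes (4), gonarthrosis
(3) and spondylosis (2) are lower than a recount of the active table (7,
6, 4). The original counting convention is undocumented; this package
does not reverse-engineer it. The published totals ship as a fixture
(`frequency_reference.csv`) and are used where a worked example cites
them. Similarly, signature-diffing the two published tables yields 15
inactive-only rules while the accompanying text enumerates 14 (it omits
the unstarred spondylosis, gonarthrosis → diabetes); both counts are
surfaced in tests.

## Descriptives

The characteristics table gives per-category n, MCD count and
percentage, with a Pearson chi-square test per categorical variable
(no continuity correction — the standard choice for k > 2 tables; the
Yates-corrected 2×2 variant is available via `correction=True`) and a
Welch t-test comparing age between MCD and non-MCD participants.
P-values below 0.001 print as "<0.001" rather than a literal zero.
Degenerate tables (a single category, or an all-zero margin such as an
all-MCD cohort) report no test.

The comorbidity network counts, over **all** participants (whether edges
should be restricted to MCD patients is unstated in the source; all
participants is the default), each disease's prevalence, the share of
its patients with MCD, and pairwise co-occurrence; only edges with at
least `min_links` (default 20) co-affected participants are kept.
Exported as edge-list CSV and GraphML.

## Synthetic cohorts

The generator emulates the 2020 survey wave the analysis assumes:
n = 8,477, 55.6% with regular exercise, 56% female, age bands 46–55 /
56–65 / 66–75 / >75 with shares 21.7 / 29.7 / 29.2 / 19.5% (uniform
integer age within band; only the band matters downstream), education
shares 29.7 / 18.3 / 32.8 / 19.1%. Disease marginals default to the
three published prevalences (hypertension 40.2%, spondylosis 18.7%,
diabetes 17.6%); the other twelve are round placeholders (not survey
values), chosen at plausible magnitudes — e.g. obesity 7%, consistent
with a lognormal BMI with median 23.5 and log-sd 0.12.

**Dependence model.** Conditions are drawn sequentially in a fixed,
configurable disease order. A planted association is a condition set
with a log-odds boost and a stratum restriction; it raises the
conditional odds of its last member (in the order) when all other
members are already present. This sequential-logistic construction was
chosen over a Gaussian copula because it gives closed-form joint
probabilities: `planted_rule_truth` enumerates the dependency closure of
any candidate rule and returns the exact model-implied P(A), P(B),
P(A, B) — hence support, confidence and lift — per stratum, plus
delta-method standard errors for finite-sample mining estimates. Note
the boost raises the *conditional* odds, so the realised marginal of a
boosted disease sits slightly above its configured baseline; the exact
truth accounts for this, and recovery tests compare mined metrics to it,
not to the baseline.

**Default plants** (the package's stated world, chosen once): couplings
among the diseases that dominate published rule tables, stronger in the
inactive stratum — hypertension–diabetes (odds ×2.2 AG, ×3.0 IG),
gonarthrosis–spondylosis (×3.0 both), obesity–gonarthrosis (×2.0 both),
hypertension–cardiovascular (×1.8 AG, ×2.5 IG), and
hypertension–depression (×2.0, IG only).

**Obesity/BMI consistency.** Obesity is drawn as a regular indicator in
the sequence; BMI is then sampled from the lognormal truncated to the
matching side of 28, and weight = BMI·height² with height ~ N(1.61,
0.09²) m. Profiles rebuilt from height/weight therefore reproduce the
planted indicator exactly. When `emit_raw_codes` is on (default), each
grouped disease is emitted as a uniformly chosen raw member code, so the
grouping path is genuinely exercised.

**What a green test does and does not establish.** The generator
reproduces marginal prevalences, stratum split, and pairwise/planted
association structure; it does not emulate survey weights, household
clustering, longitudinal linkage, missingness patterns, or age/sex
gradients in disease risk. Tests against it validate the machinery
(filtering, mining, comparison) and its statistical calibration, not the
epidemiology of the real cohort. In particular the default world's MCD
rate (~47%) is not tuned to the published 39.1%, which is recomputed
from published counts instead.

## Calibration facts the suite asserts

- Under full independence at the study thresholds, 20 seeds × n = 8,000
  yield essentially zero rules (lift must exceed 1.5 where its sampling
  sd is a few percent).
- At n = 20,000, mined support/confidence/lift of planted rules match
  the exact implied values within 3 Monte-Carlo standard errors, and an
  IG-only plant never surfaces in AG.
- Within each published rule table, support/confidence = P(antecedent)
  is constant per antecedent to within 0.0005 (table rounding).

## Limitations

- Appearance counting cannot reproduce the three undocumented published
  active-stratum antecedent counts (see above).
- No statistical testing of rule-set differences and no multiple-testing
  control over mined rules — absent from the source methodology too.
- The delta-method lift standard error ignores the (positive)
  covariance between confidence and consequent prevalence and is mildly
  conservative.
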