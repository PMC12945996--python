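# Methods

## The analysis problem

Spontaneous adverse-event databases record only what someone chose to
report.  Without exposure denominators, drug safety analysis falls back on
*disproportionality*: for a (drug, event) pair, compare how often the event
appears among the drug's reports with how often it appears among everyone
else's.  `tpopv` implements this for thromboembolic events under the three
TPO-receptor agonists used in immune thrombocytopenia, but every component
is parameterized by a drug dictionary and an event map, so nothing is
specific to that exposure class.

## Cleaning model

A patient case (`CASEID`) may appear as several report versions
(`PRIMARYID`), because follow-ups and multi-source submissions re-enter the
database.  Deduplication keeps, per case, the version with the latest
`FDA_DT`; exact date ties are broken by the highest `PRIMARYID`.  Partial
FDA dates (`YYYYMM`, `YYYY`) are ordered lexicographically at their
available precision with missing components treated as earliest — dedup
needs a total order, while time-to-onset has its own stricter completeness
rule.

Drug exposure is matched by *exact* synonym equality (case-insensitive,
whitespace-collapsed) against a generic+brand dictionary.  Substring
matching is deliberately rejected: FAERS verbatim drug strings include
combination products and free-text qualifiers that would otherwise create
false exposure matches.  The cost is that unlisted spellings are missed;
the dictionary is user-extensible.

Reports whose matched drug carries only concomitant (C) or interacting (I)
roles are excluded from the analysis universe entirely (they are neither
exposure nor comparator), mirroring standard suspect-role practice.  The
default allowed role set is {PS}; {PS, SS} is a configuration option
because reporting practice for "suspect" varies.

Event terms are mapped through a PT → (category, scope) lookup.  The
bundled file is a **synthetic stand-in** for the licensed MedDRA SMQ
dictionary: 45 thromboembolic preferred terms assigned to venous, arterial
and mixed categories by package curation.  Analyses at the category level
inherit whatever mapping the user supplies.

Age and weight units are normalized (YR/DEC/MON/WK/DY to years; KG/LBS to
kg) with plausibility windows — age in (0, 120] years, weight in (0, 500]
kg — outside which the value becomes missing with a warning, never a
silent clamp.

### Binning conventions

The printed group labels in demographic tables overlap ("18-65"/"65-85"),
so one convention is fixed, echoed into every output manifest:

* age: [0,18), [18,65), [65,85), [85,∞) years
* weight: (0,50), [50,100], (100,∞) kg
* duration: [0,365), [365,730], (730,∞) days

Missing values map to an explicit NA level; descriptive tables use
available cases with NA shown (denominators include NA so blocks sum to
100%), while the multivariable model is complete-case.

## Disproportionality statistics

For cells a, b, c, d (N = a+b+c+d), with the comparator being every
analysis case whose matched suspect drug is not the target:

* `ROR = ad/bc`, `SE(ln ROR) = √(1/a+1/b+1/c+1/d)`, 95% Wald CI on the log
  scale.  Any zero cell makes the statistic undefined (flagged, never
  continuity-corrected by default — the signal gate requires a ≥ 3, so a
  Haldane correction could only affect ungated output and would quietly
  manufacture estimates from no information).
* `PRR = [a/(a+b)]/[c/(c+d)]`, `SE(ln PRR) = √(1/a − 1/(a+b) + 1/c −
  1/(c+d))`.  The Pearson χ² of the table is computed without Yates
  correction by default (configurable).
* BCPNN information component with priors α₁=β₁=1, α=β=2, γ₁₁=1 and the
  joint-cell prior scale `γ = γ₁₁(N+α)(N+β)/[(a+b+α₁)(a+c+β₁)]`, which
  calibrates the prior to independence:

  `E(IC) = log2[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]`

  `V(IC) = (1/ln²2)·[(N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ)) +
  (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α)) + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β))]`

  These are the standard closed forms for the method; an in-repo
  Monte-Carlo oracle samples the three independent Beta posteriors implied
  by the priors and reproduces E(IC) as log2 of the ratio of posterior
  means, validating the algebra independently of the implementation.
* Strength tiers on E(IC): `−` (≤0), `+` (≤1.5), `++` (≤3), `+++` (>3).
* Association p-value: Fisher's exact test (two-sided) whenever any
  expected cell count is below 5, otherwise the χ² test with 1 df.

**Signal gate.** A pair is a suspected signal when all three methods are
positive: a ≥ 3 with the ROR lower bound > 1, a ≥ 3 with the PRR lower
bound > 1, and E(IC) > 0.  The E(IC) > 0 component follows the printed
threshold convention of the source methodology; note that on its own it is
a point-estimate sign, not a calibrated test — under independence it flips
roughly half the time for pairs with appreciable counts.  It is only ever
used inside the conjunction, whose null positivity stays below the
nominal-plus-small-count band (verified by simulation); analysts wanting a
calibrated Bayesian criterion on its own should use the
`ic_minus_2sd > 0` gate option.

## Time to onset

TTO = event onset date − therapy start date, in whole days.  A report
enters only when both dates are complete (day+month+year, real calendar
dates) and the difference is non-negative; otherwise it receives an
explicit status (`excluded_missing`, `excluded_incomplete_date`,
`excluded_negative`) and the statuses partition the input exactly.  When a
case has several therapy rows for the matched drug, the earliest complete
start date is used (initiation).  Bins are upper-inclusive integer-day
intervals matching the conventional labels (0–30 includes same-day onset
and day 30; 31–60 starts at 31; the tail is open at >360).  Quartiles use
linear interpolation between order statistics — the default in most
statistical environments; the method name is recorded in the run manifest
since quantile conventions differ.

## Risk-factor models

The outcome is per report: does it mention at least one mapped target
event?  Covariates are categorical (age, weight, sex, duration, drug) with
fixed reference levels (youngest/lightest/female/shortest/alphabetically
first drug).  Univariable fits use available cases per covariate; any
covariate with a level-wise Wald p < 0.05 enters the multivariable model,
which uses complete cases.  Fits are maximum likelihood via IRLS
(statsmodels GLM, binomial family), with identical covariate patterns
aggregated to binomial counts first, so cost scales with cells rather than
reports.  For a single categorical covariate the fitted level-vs-reference
odds ratio equals the closed-form cross-product ratio; the implementation
carries that value as a cross-check column and the tests assert agreement
to 1e-6.  Separation (a zero outcome margin for a level) is flagged as
non-estimable rather than reported as a huge unstable coefficient.
Treatment duration is computed as therapy start to event onset — the only
reading computable from the report schema — and shares the TTO validity
rules.  Wald intervals are used throughout; published comparison values are
matched on the point estimates, with interval overlap as the secondary
check, because the reference analysis does not state its CI method.

## Synthetic world

The generator emits the four-table dialect with a known joint distribution:

* ~5,000 cases by default across three TPO-RAs (shares 0.10/0.30/0.25) and
  two background drugs (0.35 combined), so every target drug has a
  non-trivial comparator.
* Eight thromboembolic PTs with background reporting probabilities from
  0.0008 to 0.01 per case, plus non-mapped filler PTs so every report has
  at least one reaction.  A planted signal multiplies one pair's
  probability; multiplier 1 everywhere is the null world used for
  calibration.
* Role codes PS/SS/C/I at 0.70/0.15/0.10/0.05; 30% of cases carry an extra
  concomitant drug row, which also exercises the role-exclusion path.
* Onset days are log-normal with median 81 days and log-sd 1.744 (chosen so
  the quartile ratio matches the reported onset profile for this drug
  class: quartiles ≈ 25/81/263 days).
* Missingness mirrors the reported demographic completeness (~30% missing
  age, ~70% missing weight, ~35%/25% missing start/event dates); 10% of
  emitted dates are partial (`YYYYMM` or `YYYY`); ages are emitted in
  YR/MON/DY/DEC units and weights in KG/LBS.
* 20% of cases emit 2–4 report versions with non-decreasing FDA dates
  (ties included so the PRIMARYID tie-break is observable); non-final
  versions mutate weight and reporter so the dedup choice is detectable.

What the generator does **not** emulate: indication confounding,
correlated comorbidity structure, notoriety/stimulated reporting waves, or
a MedDRA hierarchy beyond a flat PT list.  A green planted-signal test
therefore establishes that the pipeline recovers a known reporting-rate
distortion under realistic formatting noise — not that the method is
robust to the epidemiological biases of real spontaneous data.

## Numerical and design notes

* Determinism: one `numpy` Generator seeded from the config drives all
  sampling; identical configs give byte-identical tables.
* Zero/degenerate cells: statistics become NaN with positivity false;
  empty datasets raise immediately rather than emitting empty statistics.
* IRLS convergence: relative tolerance 1e-8, 100 iterations; models with
  fewer than 10 complete cases per parameter warn.
* The per-case event-counting unit is one deduplicated case per PT — a
  case contributes at most 1 to any a-cell regardless of repeated PT rows.
* The comparator ("other drugs") is all loaded analysis cases without the
  target drug.  With an all-drug FAERS extract this reproduces the classic
  full-database comparator; with a restricted extract it is a
  within-dataset comparator, and the choice is recorded in the manifest.

## Known limitations

* Published per-PT signal tables require the full FAERS download and are
  not reproduced numerically; fidelity is established through the
  published-marginal odds-ratio recomputations and synthetic recovery.
* The bundled SMQ-style map is a curated stand-in; category-level results
  depend on the user's licensed mapping.
* Multivariable odds ratios from published marginal tables are
  unrecoverable in principle (marginals do not determine the joint
  distribution); the model is validated by parameter-recovery simulation
  instead.
* Fisher's two-sided p and the χ² p agree closely only for large expected
  counts; at expected counts near 10² the two-sided definitions can still
  differ by ~0.05 near p = 1.
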