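# Methods

## Scores

Coverage, completeness and suitability are defined in the README; this
note records the modelling choices, defaults and numerical details.

**Category universes.** Coverage for a feature is computed over the union
of the categories observed in the trial cohort and in the target
population; categories absent from one side receive probability 0 before
ε-stabilisation. Universes are sorted lexicographically so results do not
depend on row order. Categorical values are upper-cased and trimmed
before counting; religion, language and marital status have no fixed
vocabulary (distributions are built from observed counts), while age
group, weight group, gender and ethnicity use fixed inventories.

**ε-handling.** ε = 1e-10 is added to every probability term — the
leading factor and both log arguments — without renormalising. This is a
deliberate reproduction of the stabilisation as defined, not the more
common "smooth and renormalise" scheme; it perturbs the divergence by
O(ε·log ε), far below reporting precision, and can make KL terms very
slightly negative, so totals are clamped at 0 and the JSD at [0, 1].
Identical distributions therefore score ≤ 1e-8 rather than exactly 0.

**Logarithm base.** Base 2, so JSD ≤ 1 and coverage stays in [0, 100].
The base is configurable (`WeightConfig.log_base`). Note that
general-purpose routines (e.g. `scipy.spatial.distance.jensenshannon`)
return the *square root* of the divergence, often in natural log; the
implementation here is the divergence itself, as the coverage definition
requires. The test suite uses scipy's squared base-2 distance as an
independent cross-check.

**Missing data and coverage.** Coverage distributions are built from
complete (non-missing) assignments only; incompleteness is measured
solely by the completeness metric. This keeps the two axes orthogonal,
which the independence analysis presumes. A weighted feature with *no*
valid data is a hard error by default; an opt-in flag
(`renormalise_on_missing_feature`) drops it, rescales the remaining
weights, and records the exclusion in the result rather than renormalising
silently.

**Missing-value policy.** Nulls and the explicit designations "UNKNOWN",
"PATIENT DECLINED", "UNABLE TO OBTAIN" (plus empty strings and
"NOT SPECIFIED") count as incomplete; matching is case-insensitive and
whitespace-trimmed, and the set is configurable. A granular ethnicity
label that consolidates to the "Unknown" major group is likewise counted
as incomplete — recording "unknown" is a data-quality fact, not a
demographic category — and is correspondingly excluded from the ethnicity
coverage distribution.

**Interval convention.** The age and weight group boundaries overlap as
colloquially stated ("1–18", "18–40", ...); all bins here are half-open
[lower, upper), so age 18 is Young Adult, 65 Older Adult, 80 Elderly, and
weight 50 kg is Normal, 120 kg Severely Obese. This is a choice made for
exhaustiveness and testability, not a convention inherited from any
particular dataset.

**Weights.** Defaults: age 0.30, gender 0.25, ethnicity 0.20, weight
0.10, religion/language/marital status 0.05, reflecting clinical and
regulatory convention (age, gender and ethnicity as primary determinants
of pharmacological response); aggregation 0.60 coverage / 0.40
completeness, favouring coverage because demographic misalignment limits
external validity in ways that statistical missing-data methods cannot
repair. Both are configuration, not constants: `WeightConfig` validates
that feature weights are non-negative and sum to 1 and that the
aggregation pair sums to 1. Percentages are carried at full precision
and rounded to one decimal only for display.

## Synthetic populations

The generator emulates a critical-care EHR demographics export. Per
field it draws from a configurable categorical distribution (defaults:
gender near-even; ethnicity dominated by White with Black/African
American, Hispanic/Latino, Asian, Other and Multiple minorities; common
hospital religion/language/marital inventories). Age and weight are
Gaussian mixtures, clipped and later binned — the default age mixture
(0.85·N(66, 16) + 0.15·N(35, 10), clipped to [0, 105]) places most mass
in the older-adult range typical of ICU treatment populations; weight is
N(82, 22) clipped to [35, 180] kg. Missingness is overlaid per feature as
true nulls (`missing_rates`) and explicit unknown designations
(`unknown_rates`); the default profile reproduces the documented quality
pattern of such exports — weight ≈ 47 % complete, language ≈ 68 %, age
≈ 95 %, other features complete.

What the generator does **not** model: clinical covariates, comorbidity
structure, correlations between demographics and missingness
(missingness is independent per feature and per patient), temporal or
site effects, and free-text label noise beyond the fixed inventories.
Passing tests therefore demonstrate the framework's behaviour under
controlled demographic structure and missingness, not its behaviour on
any particular real dataset.

**Designed shifts.** `shifted_spec(spec, delta)` moves probability mass
`delta` (a total-variation distance) onto the first gender label and
shifts the age-mixture means by 30·delta years, giving a one-parameter
family of pool-vs-target divergences on two high-weight features. The
end-to-end tests sweep delta over {0, 0.06, 0.12, 0.18, 0.24} and check
that mean coverage decreases monotonically.

## Validation study

Cohort sizes are drawn from N(60, 13), rounded to the nearest integer,
then clipped to [20, 100] — single-centre Phase II/III enrolment scale.
Cohorts are simple random samples without replacement from a pool
disjoint from the target (enforced on patient ids). Per-cohort seeds
derive deterministically from the base seed (base + 1 + index), and the
pool is sorted by patient id before every draw, so a study is
reproducible from one integer and immune to incidental row-ordering of
its inputs. Summary statistics use the sample SD (n−1). The
unique-selection rate — distinct patients used over total selections —
quantifies cohort overlap; it depends directly on the pool size, so its
value is reported but not comparable across pools of different size.

Default problem sizes in the tests and examples (pool 1 500–4 000,
target 800–1 315, 25–100 cohorts) were chosen as the smallest scales at
which the binomial sampling error of the checked statistics is well
inside the asserted margins.

## Independence and robustness

Coverage/completeness independence and size/score association use
Pearson and Spearman correlations with two-sided p-values from the
t-approximation (standard at n = 100; an exact approach is unnecessary
at that scale). |r| < 0.3 is reported as "weak" (metrics capture
distinct aspects; combining them is justified), |r| > 0.7 as "strong"
(one metric would suffice).

The robustness engine re-aggregates frozen per-cohort per-feature scores
under named weight configurations — it never resamples, so scenario
differences reflect the weights alone. Built-in scenarios: clinical,
equal (1/7 each), age-dominant, and aggregation splits 70/30, 60/40,
50/50. "Age-dominant" assigns 0.50 to age and rescales the other six
clinical weights proportionally to sum to 0.50, preserving their
relative priorities (the redistribution rule is otherwise
underdetermined). Best/worst cohorts are argmax/argmin of suitability
with ties broken toward the lowest cohort index and flagged explicitly.

## Known limitations

- The clinical feature weights and the 60/40 aggregation are informed
  design choices, not empirically derived; the robustness engine exists
  precisely to probe sensitivity to them.
- Coverage treats categories as unordered even for binned age/weight: a
  cohort one bin away scores the same as one three bins away.
- Completeness is per-feature; joint missingness patterns (records
  missing several fields at once) are not distinguished.
- The ethnicity consolidation ships a default prefix mapping; deployments
  with other label vocabularies must supply their own mapping or a
  fallback group (unmapped labels fail loudly by design).
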