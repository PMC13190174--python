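# trialfit

Quantitative assessment of how well a clinical-trial cohort represents a
target treatment population.

Regulatory guidance increasingly asks trial designers to show that an
enrolled cohort resembles the population that will actually receive a
treatment. `trialfit` turns that question into numbers, for trial
designers, pharmacoepidemiologists and data-quality teams working from
EHR-style demographics tables (one row per patient: age, gender,
ethnicity, weight, language, religion, marital status).

## The model

For each of seven demographic features *f*, category distributions are
estimated from counts in the trial cohort and the target population:

    p_trial^f(c) = n_trial^f(c) / Σ_c' n_trial^f(c')

**Coverage** measures demographic similarity via the Jensen–Shannon
divergence to the midpoint distribution M^f = (p_trial^f + p_target^f)/2,
with base-2 logarithms so JSD ∈ [0, 1] and a stabiliser ε = 1e-10 added to
every probability term:

    JSD^f     = ½·KL(p_trial^f ‖ M^f) + ½·KL(p_target^f ‖ M^f)
    Coverage^f = (1 − JSD^f) × 100 %

**Completeness** measures data availability per feature:

    Completeness^f = (n_total − n_missing^f − n_unknown^f) / n_total × 100 %

where explicit designations ("UNKNOWN", "PATIENT DECLINED", "UNABLE TO
OBTAIN") count as incomplete alongside nulls. Per-feature scores are
aggregated with clinical weights w_f — age 0.30, gender 0.25, ethnicity
0.20, weight 0.10, religion/language/marital status 0.05 each — and
combined:

    Suitability = 0.60·Coverage_overall + 0.40·Completeness_overall

Continuous features are binned first: age into six clinically motivated
groups (Neonate/Infant < 1 y, Child/Adolescent 1–18, Young Adult 18–40,
Middle-aged 40–65, Older Adult 65–80, Elderly 80+) and weight into five
dosing-relevant groups (< 50, 50–70, 70–90, 90–120, ≥ 120 kg). All
intervals are half-open `[lower, upper)`, so every boundary value belongs
to the upper group. Granular ethnicity labels are consolidated into seven
major groups via a configurable prefix mapping.

Around the metric sit a synthetic-population generator (configurable
category probabilities and per-feature missingness, emulating an EHR
export), a validation-study driver (100 cohorts with Gaussian sizes,
mean 60, SD 13, clipped to 20–100, sampled without replacement), metric
independence checks (Pearson/Spearman), and a weight-robustness engine
that re-aggregates frozen per-feature scores under alternative weighting
scenarios.

## Worked example

`python examples/worked_example.py` aggregates a hypothetical cohort's
per-feature scores:

```
overall coverage:     90.525%
overall completeness: 88.1%
suitability (full-precision coverage): 89.6%
suitability (coverage rounded to 90):  89.2%
```

The weighted completeness of the printed profile is exactly 88.1 %. The
full-precision weighted coverage is 90.525 %; when that is rounded to 90 %
before the final 60/40 combination — as summary tables conventionally do —
the suitability is 89.2 %. `trialfit` carries all scores at full precision
internally and rounds only for display.

Other narrative examples in `examples/`: `score_two_tables.py` (CSV in,
suitability out), `simulation_study.py` (full 100-cohort study with
independence checks), `robustness_scenarios.py` (weight-scenario table),
`radar_profiles.py` (per-feature radar data export and plot).

The same capabilities are exposed as a small CLI:

```
trialfit score --trial trial.csv --target target.csv --out results/
trialfit simulate --n-cohorts 100 --seed 7 --out results/
trialfit robustness --scores results/cohort_scores.csv --out results/
trialfit make-population --n 4000 --seed 1 --out pop.csv
```

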