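"""Export per-feature radar-plot data for the best and worst cohorts.

Produces the long-format (entity, feature, metric, value) table behind the
coverage / completeness / suitability radar figures; the target's coverage is
100% per feature by definition (it is compared with itself).
"""

import tempfile
from pathlib import Path

from trialfit import (
    CohortSamplingConfig,
    Feature,
    featurize,
    generate_population,
    identify_extremes,
    mimic_like_spec,
    run_validation_study,
)
from trialfit.io import export_radar_data, plot_radar

pool = generate_population(mimic_like_spec(2000, seed=27, id_prefix="N"))
target = generate_population(mimic_like_spec(1000, seed=28, id_prefix="T"))
study = run_validation_study(pool, target, CohortSamplingConfig(n_cohorts=30, seed=29))
best, worst, _, _ = identify_extremes(study.results)

target_table = featurize(target)
target_completeness = {
    f: 100.0 * (1.0 - target_table[f.value].isna().mean()) for f in Feature
}
radar = export_radar_data([best, worst], target_completeness)
print(radar.head(12).to_string(index=False))
print(f"... {len(radar)} rows total (3 entities x 3 metrics x 7 features)")

out = Path(tempfile.mkdtemp()) / "coverage_radar.png"
plot_radar(radar, "coverage", out, title="Coverage profile")
print(f"rendered {out}")
# Each row is one spoke value of a radar plot; the target traces the outer
# 100% boundary for coverage, while its completeness spokes dip where the
# source data are incomplete (weight, language).
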