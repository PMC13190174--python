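"""Metric-independence checks, extreme-cohort identification, weight robustness.

The composite suitability score presumes that coverage and completeness
capture distinct aspects of cohort quality; :func:`correlation_check`
quantifies this with Pearson and Spearman correlations (|r| < 0.3 is read
as weak/independent, |r| > 0.7 as strong/redundant).  The robustness
engine re-aggregates frozen per-cohort per-feature scores under
alternative weight configurations — it never resamples — and reports, per
scenario, the suitability summary statistics and the best/worst cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demographics import Feature
from .errors import ConfigError, EmptyCohortError, UndefinedCorrelationError
from .metrics import (
    CLINICAL_FEATURE_WEIGHTS,
    SuitabilityResult,
    WeightConfig,
    aggregate,
    suitability,
)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson and Spearman correlations with an independence verdict."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    independence_verdict: str  # weak | moderate | strong

    @staticmethod
    def verdict_for(r: float) -> str:
        if abs(r) < 0.3:
            return "weak"
        if abs(r) > 0.7:
            return "strong"
        return "moderate"


@dataclass(frozen=True)
class ScenarioResult:
    """Summary of one weighting scenario over a fixed cohort set."""

    scenario: str
    weights: WeightConfig
    mean: float
    sd: float
    min: float
    max: float
    best_cohort: str
    worst_cohort: str
    best_tie: bool = False
    worst_tie: bool = False


def correlation_check(
    coverages: Sequence[float], completenesses: Sequence[float]
) -> CorrelationReport:
    """Pearson + Spearman correlation between two score vectors.

    Two-sided p-values via the t-distribution approximation.  Raises
    :class:`UndefinedCorrelationError` on constant input.
    """
    x = np.asarray(coverages, dtype=float)
    y = np.asarray(completenesses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("score vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ConfigError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationReport(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n=len(x),
        independence_verdict=CorrelationReport.verdict_for(float(pr.statistic)),
    )


def size_association(sizes: Sequence[int], scores: Sequence[float]) -> CorrelationReport:
    """Association between cohort size and a score (same contract as correlation_check)."""
    return correlation_check([float(s) for s in sizes], scores)


def identify_extremes(
    results: Sequence[SuitabilityResult],
) -> tuple[SuitabilityResult, SuitabilityResult, bool, bool]:
    """Best and worst cohorts by suitability; ties broken by lowest index.

    Returns ``(best, worst, best_tie, worst_tie)`` where the tie flags
    report whether another cohort achieved the same extreme value.
    """
    if len(results) == 0:
        raise EmptyCohortError("cannot identify extremes of an empty result list")
    values = [r.suitability for r in results]
    best_i = int(np.argmax(values))
    worst_i = int(np.argmin(values))
    best_tie = values.count(values[best_i]) > 1
    worst_tie = values.count(values[worst_i]) > 1
    return results[best_i], results[worst_i], best_tie, worst_tie


def _age_dominant_weights() -> dict[Feature, float]:
    # 0.50 to age; the other six clinical weights rescaled proportionally to 0.50
    others = {f: w for f, w in CLINICAL_FEATURE_WEIGHTS.items() if f is not Feature.AGE_GROUP}
    total = sum(others.values())
    weights = {f: 0.50 * w / total for f, w in others.items()}
    weights[Feature.AGE_GROUP] = 0.50
    return weights


def builtin_scenarios() -> dict[str, WeightConfig]:
    """The named weight configurations of the standard robustness analysis.

    Feature-weight scenarios (aggregation fixed at 60/40): clinical, equal
    (1/7 each), age-dominant (0.50 on age, rest proportional).
    Aggregation-weight scenarios (clinical feature weights): 70/30, 60/40,
    50/50.
    """
    equal = {f: 1.0 / 7.0 for f in Feature}
    clinical = dict(CLINICAL_FEATURE_WEIGHTS)
    return {
        "clinical": WeightConfig(clinical, 0.60, 0.40),
        "equal": WeightConfig(equal, 0.60, 0.40),
        "age_dominant": WeightConfig(_age_dominant_weights(), 0.60, 0.40),
        "coverage_dominant_70_30": WeightConfig(clinical, 0.70, 0.30),
        "current_60_40": WeightConfig(clinical, 0.60, 0.40),
        "equal_50_50": WeightConfig(clinical, 0.50, 0.50),
    }


def rescore(result: SuitabilityResult, weights: WeightConfig) -> float:
    """Suitability of one cohort under alternative weights (re-aggregation only)."""
    cov = aggregate(result.feature_coverage, weights.feature_weights)
    comp = aggregate(result.feature_completeness, weights.feature_weights)
    return suitability(cov, comp, weights)


def run_robustness(
    results: Sequence[SuitabilityResult],
    scenarios: Mapping[str, WeightConfig] | None = None,
) -> list[ScenarioResult]:
    """Re-score a fixed cohort set under each weighting scenario.

    Only the aggregation step is re-run; the per-feature coverage and
    completeness scores are frozen, so scenario differences reflect the
    weights alone.  Sample SD (n-1) is reported.
    """
    if len(results) == 0:
        raise EmptyCohortError("no cohorts to re-score")
    if scenarios is None:
        scenarios = builtin_scenarios()
    out: list[ScenarioResult] = []
    for name, cfg in scenarios.items():
        values = [rescore(r, cfg) for r in results]
        arr = np.asarray(values)
        best_i = int(np.argmax(values))
        worst_i = int(np.argmin(values))
        out.append(
            ScenarioResult(
                scenario=name,
                weights=cfg,
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                min=float(arr.min()),
                max=float(arr.max()),
                best_cohort=results[best_i].cohort_id,
                worst_cohort=results[worst_i].cohort_id,
                best_tie=values.count(values[best_i]) > 1,
                worst_tie=values.count(values[worst_i]) > 1,
            )
        )
    return out


def robustness_table(scenario_results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Long-format summary matching the standard report layout."""
    return pd.DataFrame(
        [
            {
                "Scenario": s.scenario,
                "Mean": s.mean,
                "SD": s.sd,
                "Min": s.min,
                "Max": s.max,
                "Best": s.best_cohort,
                "Worst": s.worst_cohort,
            }
            for s in scenario_results
        ]
    )
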