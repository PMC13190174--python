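"""Coverage, completeness and suitability metrics.

Coverage of a feature is defined from the Jensen–Shannon divergence (JSD)
between the trial cohort's and the target population's category
distributions::

    p_trial(c) = n_trial(c) / sum_c' n_trial(c')        (counts over the
    p_target(c) likewise                                 shared universe)
    M(c)   = (p_trial(c) + p_target(c)) / 2
    KL(p||M) = sum_c (p(c)+eps) * log2((p(c)+eps) / (M(c)+eps))
    JSD    = KL(p_trial||M)/2 + KL(p_target||M)/2
    Coverage = (1 - JSD) * 100

With base-2 logarithms the JSD lies in [0, 1], so coverage lies in
[0, 100].  A small constant eps (default 1e-10) is added to every
probability term before the logarithms, without renormalising, to keep the
computation defined when categories have zero probability.  Note that
general-purpose routines often return the *square root* of the divergence
and/or use natural logarithms; neither matches the definition above.

Completeness of a feature is the percentage of records with a valid value::

    Completeness = (n_total - n_missing - n_unknown) / n_total * 100

Per-feature scores are aggregated by a convex weight vector over the seven
features, and the overall suitability is a convex combination of overall
coverage and overall completeness (default 0.60 / 0.40).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demographics import (
    Feature,
    FeatureSpec,
    MissingPolicy,
    PatientRecord,
    default_schema,
    featurize,
)
from .errors import (
    ConfigError,
    EmptyCohortError,
    IncompleteScoresError,
    NoValidDataError,
    ShapeError,
)

#: Clinically informed default feature weights: age, gender and ethnicity
#: dominate as primary determinants of pharmacological response.
CLINICAL_FEATURE_WEIGHTS: dict[Feature, float] = {
    Feature.AGE_GROUP: 0.30,
    Feature.GENDER: 0.25,
    Feature.ETHNICITY: 0.20,
    Feature.WEIGHT_GROUP: 0.10,
    Feature.RELIGION: 0.05,
    Feature.LANGUAGE: 0.05,
    Feature.MARITAL_STATUS: 0.05,
}

DEFAULT_EPSILON = 1e-10


@dataclass(frozen=True)
class WeightConfig:
    """Feature weights plus the coverage/completeness aggregation weights."""

    feature_weights: Mapping[Feature, float] = field(
        default_factory=lambda: dict(CLINICAL_FEATURE_WEIGHTS)
    )
    coverage_weight: float = 0.60
    completeness_weight: float = 0.40
    epsilon: float = DEFAULT_EPSILON
    log_base: float = 2.0

    def __post_init__(self) -> None:
        fw = {Feature(k): float(v) for k, v in self.feature_weights.items()}
        object.__setattr__(self, "feature_weights", fw)
        if any(w < 0 for w in fw.values()):
            raise ConfigError("feature weights must be non-negative")
        if abs(sum(fw.values()) - 1.0) > 1e-9:
            raise ConfigError(f"feature weights must sum to 1, got {sum(fw.values())}")
        if abs(self.coverage_weight + self.completeness_weight - 1.0) > 1e-9:
            raise ConfigError("coverage_weight + completeness_weight must equal 1")
        if self.coverage_weight < 0 or self.completeness_weight < 0:
            raise ConfigError("aggregation weights must be non-negative")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.log_base <= 1:
            raise ConfigError("log_base must exceed 1")


@dataclass(frozen=True)
class FeatureDistribution:
    """Normalised category-probability vector for one feature in one cohort."""

    feature: Feature
    categories: tuple[str, ...]
    probs: tuple[float, ...]
    n_complete: int

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.probs):
            raise ShapeError("categories and probs must have equal length")
        if len(set(self.categories)) != len(self.categories):
            raise ShapeError("categories must be unique")
        if any(p < 0 for p in self.probs):
            raise ShapeError("probabilities must be non-negative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ShapeError(f"probabilities must sum to 1, got {sum(self.probs)}")


@dataclass
class SuitabilityResult:
    """Per-feature and overall scores for one trial-vs-target comparison.

    All percentages are carried at full precision; round only for display.
    """

    cohort_id: str
    cohort_size: int
    feature_coverage: dict[Feature, float]
    feature_completeness: dict[Feature, float]
    coverage_overall: float
    completeness_overall: float
    suitability: float
    excluded_features: tuple[Feature, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "cohort_id": self.cohort_id,
            "cohort_size": self.cohort_size,
            "coverage_overall": self.coverage_overall,
            "completeness_overall": self.completeness_overall,
            "suitability": self.suitability,
        }
        for f in Feature:
            d[f"coverage_{f.value}"] = self.feature_coverage.get(f)
            d[f"completeness_{f.value}"] = self.feature_completeness.get(f)
        if self.excluded_features:
            d["excluded_features"] = ",".join(f.value for f in self.excluded_features)
        return d


def category_distribution(
    assignments: pd.DataFrame,
    feature: Feature | str,
    category_universe: Sequence[str],
) -> FeatureDistribution:
    """Empirical category distribution of one feature over a shared universe.

    Counts non-missing assignments and normalises; categories of the
    universe absent from the cohort receive probability 0.  Raises
    :class:`NoValidDataError` when every assignment is missing.
    """
    feature = Feature(feature)
    col = assignments[feature.value].dropna()
    if len(col) == 0:
        raise NoValidDataError(feature.value)
    counts = col.value_counts()
    unseen = set(counts.index) - set(category_universe)
    if unseen:
        raise ShapeError(f"categories {sorted(unseen)} not in the given universe")
    total = int(counts.sum())
    probs = tuple(float(counts.get(c, 0)) / total for c in category_universe)
    return FeatureDistribution(feature, tuple(category_universe), probs, total)


def kl_divergence(
    p: Sequence[float],
    m: Sequence[float],
    epsilon: float = DEFAULT_EPSILON,
    base: float = 2.0,
) -> float:
    """Epsilon-stabilised Kullback–Leibler divergence, in bits by default.

    Every probability term (the leading factor and both log arguments) gets
    ``epsilon`` added, without renormalising; the tiny negative totals this
    can induce are clamped to 0.
    """
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    if p.shape != m.shape or p.ndim != 1:
        raise ShapeError(f"shape mismatch: {p.shape} vs {m.shape}")
    if (p < 0).any() or (m < 0).any():
        raise ShapeError("probabilities must be non-negative")
    terms = (p + epsilon) * (np.log(p + epsilon) - np.log(m + epsilon)) / np.log(base)
    return max(0.0, float(terms.sum()))


def jsd(
    p_trial: FeatureDistribution | Sequence[float],
    p_target: FeatureDistribution | Sequence[float],
    epsilon: float = DEFAULT_EPSILON,
    base: float = 2.0,
) -> float:
    """Jensen–Shannon divergence between two distributions on one universe.

    Symmetric and, with base-2 logarithms, bounded by [0, 1]; ~0 for
    identical distributions and 1 for disjoint support.  Accepts either
    :class:`FeatureDistribution` objects (whose universes must match) or
    bare probability vectors.
    """
    if isinstance(p_trial, FeatureDistribution) and isinstance(p_target, FeatureDistribution):
        if p_trial.categories != p_target.categories:
            raise ShapeError("distributions are defined on different category universes")
        p, q = np.asarray(p_trial.probs), np.asarray(p_target.probs)
    else:
        p = np.asarray(p_trial, dtype=float)
        q = np.asarray(p_target, dtype=float)
    if p.shape != q.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {q.shape}")
    m = (p + q) / 2.0
    value = 0.5 * kl_divergence(p, m, epsilon, base) + 0.5 * kl_divergence(q, m, epsilon, base)
    return min(1.0, max(0.0, value))


def feature_coverage(jsd_value: float) -> float:
    """Coverage percentage, ``(1 - JSD) * 100``; strictly decreasing in JSD."""
    if not 0.0 <= jsd_value <= 1.0:
        raise ShapeError(f"jsd must lie in [0, 1], got {jsd_value}")
    return (1.0 - jsd_value) * 100.0


def feature_completeness(n_total: int, n_missing: int, n_unknown: int = 0) -> float:
    """Completeness percentage: valid records over total records.

    ``n_missing`` counts nulls, ``n_unknown`` explicit unknown
    designations; both are incomplete.
    """
    if n_total <= 0:
        raise EmptyCohortError("completeness undefined for an empty cohort")
    if n_missing < 0 or n_unknown < 0 or n_missing + n_unknown > n_total:
        raise ShapeError("counts must satisfy 0 <= n_missing + n_unknown <= n_total")
    return (n_total - n_missing - n_unknown) / n_total * 100.0


def aggregate(
    per_feature_scores: Mapping[Feature | str, float],
    feature_weights: Mapping[Feature | str, float] | None = None,
    renormalise: bool = False,
) -> float:
    """Weighted sum of per-feature percentages (a convex combination).

    Every feature carrying nonzero weight must have a score; with
    ``renormalise=True`` the weights of missing features are instead
    dropped and the rest rescaled to sum to 1.
    """
    if feature_weights is None:
        feature_weights = CLINICAL_FEATURE_WEIGHTS
    weights = {Feature(k): float(v) for k, v in feature_weights.items()}
    scores = {Feature(k): float(v) for k, v in per_feature_scores.items()}
    missing = [f for f, w in weights.items() if w > 0 and f not in scores]
    if missing:
        if not renormalise:
            raise IncompleteScoresError(
                f"no score for weighted feature(s): {[f.value for f in missing]}"
            )
        weights = {f: w for f, w in weights.items() if f in scores}
        total = sum(weights.values())
        if total <= 0:
            raise IncompleteScoresError("no weighted feature has a score")
        weights = {f: w / total for f, w in weights.items()}
    return sum(w * scores[f] for f, w in weights.items() if w > 0)


def suitability(
    coverage_overall: float,
    completeness_overall: float,
    weights: WeightConfig | None = None,
) -> float:
    """Combined suitability: convex combination of overall coverage and completeness."""
    if weights is None:
        weights = WeightConfig()
    for v in (coverage_overall, completeness_overall):
        if not 0.0 <= v <= 100.0:
            raise ShapeError(f"overall scores must lie in [0, 100], got {v}")
    return weights.coverage_weight * coverage_overall + weights.completeness_weight * completeness_overall


def _completeness_from_assignments(assignments: pd.DataFrame) -> dict[Feature, float]:
    return {
        f: feature_completeness(len(assignments), int(assignments[f.value].isna().sum()))
        for f in Feature
        if f.value in assignments.columns
    }


def score_cohort(
    trial: Sequence[PatientRecord] | pd.DataFrame,
    target: Sequence[PatientRecord] | pd.DataFrame,
    schema: Sequence[FeatureSpec] | None = None,
    policy: MissingPolicy | None = None,
    weights: WeightConfig | None = None,
    cohort_id: str = "trial",
    renormalise_on_missing_feature: bool = False,
) -> SuitabilityResult:
    """Score one trial cohort against a target population through the full chain.

    Accepts raw :class:`PatientRecord` lists (featurized internally) or
    pre-featurized assignment tables.  Coverage distributions are built from
    complete assignments only, over the union of trial and target observed
    categories; incompleteness affects only the completeness scores.
    """
    if weights is None:
        weights = WeightConfig()
    if schema is None:
        schema = default_schema()

    trial_a = trial if isinstance(trial, pd.DataFrame) else featurize(trial, schema, policy)
    target_a = target if isinstance(target, pd.DataFrame) else featurize(target, schema, policy)
    if len(trial_a) == 0 or len(target_a) == 0:
        raise EmptyCohortError("both cohorts must be non-empty")

    cov: dict[Feature, float] = {}
    excluded: list[Feature] = []
    for spec in schema:
        f = spec.name
        universe = sorted(
            set(trial_a[f.value].dropna().unique()) | set(target_a[f.value].dropna().unique())
        )
        try:
            p = category_distribution(trial_a, f, universe)
            q = category_distribution(target_a, f, universe)
        except NoValidDataError:
            if renormalise_on_missing_feature and weights.feature_weights.get(f, 0) > 0:
                excluded.append(f)
                continue
            raise
        cov[f] = feature_coverage(jsd(p, q, weights.epsilon, weights.log_base))

    comp = _completeness_from_assignments(trial_a)
    for f in excluded:
        comp.pop(f, None)

    cov_overall = aggregate(cov, weights.feature_weights, renormalise=bool(excluded))
    comp_overall = aggregate(comp, weights.feature_weights, renormalise=bool(excluded))
    return SuitabilityResult(
        cohort_id=cohort_id,
        cohort_size=len(trial_a),
        feature_coverage=cov,
        feature_completeness=comp,
        coverage_overall=cov_overall,
        completeness_overall=comp_overall,
        suitability=suitability(cov_overall, comp_overall, weights),
        excluded_features=tuple(excluded),
    )
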