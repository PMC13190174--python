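"""Coverage, completeness and suitability: examples, oracles, properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from trialfit.demographics import Feature, featurize
from trialfit.errors import (
    ConfigError,
    EmptyCohortError,
    IncompleteScoresError,
    NoValidDataError,
    ShapeError,
)
from trialfit.metrics import (
    CLINICAL_FEATURE_WEIGHTS,
    FeatureDistribution,
    WeightConfig,
    aggregate,
    category_distribution,
    feature_completeness,
    feature_coverage,
    jsd,
    kl_divergence,
    score_cohort,
    suitability,
)
from conftest import make_record

EPS = 1e-10


def brute_force_jsd(p, q, eps=EPS):
    """Independent oracle: plain-python epsilon-stabilised JSD, base-2 logs."""
    m = [(pi + qi) / 2 for pi, qi in zip(p, q)]

    def kl(a, b):
        return sum((ai + eps) * math.log2((ai + eps) / (bi + eps)) for ai, bi in zip(a, b))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def probs(n):
    """Strategy: probability vectors of length n."""
    return st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=n, max_size=n
    ).map(lambda xs: [x / s if (s := sum(xs)) > 0 else 1.0 / len(xs) for x in xs])


class TestKL:
    def test_hand_computed_value(self):
        # 0.5*log2(4/3) + 0.5*log2(4/5)
        assert kl_divergence([0.5, 0.5], [0.375, 0.625]) == pytest.approx(0.046554, abs=1e-6)

    def test_identity_is_zero(self):
        assert kl_divergence([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_one_bit(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            kl_divergence([0.5, 0.5], [1.0])


class TestJSD:
    def test_hand_computed_value(self):
        assert jsd([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.048795, abs=1e-6)

    def test_disjoint_support_is_one(self):
        assert jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-6)

    @given(probs(4))
    @settings(max_examples=100, derandomize=True)
    def test_identity_near_zero(self, p):
        assert jsd(p, p) <= 1e-8

    @given(probs(3), probs(3))
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_and_bounds(self, p, q):
        a, b = jsd(p, q), jsd(q, p)
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0

    @given(st.integers(2, 5).flatmap(lambda n: st.tuples(probs(n), probs(n))))
    @settings(max_examples=150, derandomize=True)
    def test_brute_force_oracle(self, pq):
        """Library JSD equals an independent plain-python summation."""
        p, q = pq
        assert jsd(p, q) == pytest.approx(max(0.0, min(1.0, brute_force_jsd(p, q))), abs=1e-9)

    @given(st.integers(2, 5).flatmap(lambda n: st.tuples(probs(n), probs(n))))
    @settings(max_examples=100, derandomize=True)
    def test_scipy_cross_check(self, pq):
        """Squared base-2 scipy Jensen-Shannon distance matches (eps-level slack)."""
        p, q = pq
        expected = jensenshannon(np.asarray(p), np.asarray(q), base=2) ** 2
        if math.isnan(expected):  # scipy yields nan for the zero-vector corner
            return
        assert jsd(p, q) == pytest.approx(float(expected), abs=1e-6)

    def test_universe_mismatch_rejected(self):
        d1 = FeatureDistribution(Feature.GENDER, ("Male", "Female"), (0.5, 0.5), 10)
        d2 = FeatureDistribution(Feature.GENDER, ("Female", "Male"), (0.5, 0.5), 10)
        with pytest.raises(ShapeError):
            jsd(d1, d2)


class TestDistributions:
    def test_normalisation_over_universe(self, complete_cohort):
        table = featurize(complete_cohort)
        dist = category_distribution(table, Feature.GENDER, ["FEMALE", "MALE"])
        assert dist.probs == (pytest.approx(1 / 3), pytest.approx(2 / 3))
        assert dist.n_complete == 6

    def test_zero_count_category_retained(self, complete_cohort):
        table = featurize(complete_cohort)
        dist = category_distribution(table, Feature.RELIGION, ["CATHOLIC", "JEWISH", "NONE"])
        assert dist.probs[2] == 0.0
        assert sum(dist.probs) == pytest.approx(1.0)

    def test_all_missing_raises_naming_feature(self):
        table = featurize([make_record("Z1", religion=None)])
        with pytest.raises(NoValidDataError, match="RELIGION"):
            category_distribution(table, Feature.RELIGION, ["CATHOLIC"])


class TestCoverageCompleteness:
    @pytest.mark.parametrize("j,expected", [(0.0, 100.0), (1.0, 0.0), (0.048795, 95.1205)])
    def test_feature_coverage(self, j, expected):
        assert feature_coverage(j) == pytest.approx(expected)

    def test_coverage_domain_error(self):
        with pytest.raises(ShapeError):
            feature_coverage(1.5)

    @pytest.mark.parametrize(
        "total,missing,unknown,expected",
        [(10, 2, 1, 70.0), (10, 0, 0, 100.0), (4, 4, 0, 0.0)],
    )
    def test_feature_completeness(self, total, missing, unknown, expected):
        assert feature_completeness(total, missing, unknown) == pytest.approx(expected)

    def test_empty_cohort_error(self):
        with pytest.raises(EmptyCohortError):
            feature_completeness(0, 0, 0)


WORKED_COMPLETENESS = {
    Feature.AGE_GROUP: 89.0,
    Feature.ETHNICITY: 95.0,
    Feature.GENDER: 100.0,
    Feature.WEIGHT_GROUP: 62.0,
    Feature.RELIGION: 80.0,
    Feature.LANGUAGE: 56.0,
    Feature.MARITAL_STATUS: 88.0,
}
WORKED_COVERAGE = {
    Feature.GENDER: 98.0,
    Feature.AGE_GROUP: 91.0,
    Feature.ETHNICITY: 89.0,
    Feature.WEIGHT_GROUP: 86.0,
    Feature.RELIGION: 82.5,
    Feature.LANGUAGE: 79.0,
    Feature.MARITAL_STATUS: 85.0,
}


class TestAggregation:
    def test_worked_completeness_example(self):
        assert aggregate(WORKED_COMPLETENESS) == pytest.approx(88.1)

    def test_worked_coverage_weighted_sum(self):
        # full-precision weighted sum; reported elsewhere rounded to 90
        assert aggregate(WORKED_COVERAGE) == pytest.approx(90.525)

    def test_all_equal_scores(self):
        assert aggregate({f: 100.0 for f in Feature}) == pytest.approx(100.0)

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=7, max_size=7))
    @settings(max_examples=100, derandomize=True)
    def test_convexity(self, scores):
        """Overall score lies between the per-feature min and max."""
        d = dict(zip(Feature, scores))
        agg = aggregate(d)
        assert min(scores) - 1e-9 <= agg <= max(scores) + 1e-9

    @given(st.sampled_from(list(Feature)), st.floats(0.5, 30))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_each_weighted_feature(self, feature, bump):
        base = {f: 50.0 for f in Feature}
        bumped = {**base, feature: min(100.0, 50.0 + bump)}
        assert aggregate(bumped) > aggregate(base)

    def test_missing_weighted_feature_raises(self):
        scores = {f: 90.0 for f in Feature if f is not Feature.AGE_GROUP}
        with pytest.raises(IncompleteScoresError):
            aggregate(scores)

    def test_renormalisation_option(self):
        scores = {f: 90.0 for f in Feature if f is not Feature.AGE_GROUP}
        assert aggregate(scores, renormalise=True) == pytest.approx(90.0)


class TestSuitability:
    def test_worked_example(self):
        assert round(suitability(90.0, 88.1), 1) == 89.2

    @pytest.mark.parametrize("cov,comp,expected", [(100, 100, 100.0), (0, 100, 40.0)])
    def test_corners(self, cov, comp, expected):
        assert suitability(cov, comp) == pytest.approx(expected)

    def test_weight_config_invariants(self):
        with pytest.raises(ConfigError):
            WeightConfig(coverage_weight=0.7, completeness_weight=0.4)
        with pytest.raises(ConfigError):
            WeightConfig(feature_weights={Feature.AGE_GROUP: 1.5})
        with pytest.raises(ConfigError):
            WeightConfig(epsilon=0)


class TestScoreCohort:
    def test_self_comparison_is_perfect(self, target_cohort):
        mirrored = [make_record(f"M{i}", age=r.age, gender=r.gender, weight=r.weight)
                    for i, r in enumerate(target_cohort)]
        res = score_cohort(mirrored, target_cohort)
        assert res.coverage_overall == pytest.approx(100.0, abs=1e-6)
        assert res.completeness_overall == pytest.approx(100.0)
        assert res.suitability == pytest.approx(100.0, abs=1e-6)

    def test_locality_of_a_single_feature_shift(self, target_cohort):
        shifted = [make_record(f"S{i}", age=r.age, gender="Female", weight=r.weight)
                   for i, r in enumerate(target_cohort)]
        res = score_cohort(shifted, target_cohort)
        assert res.feature_coverage[Feature.GENDER] < 100.0 - 1e-6
        for f in Feature:
            if f is not Feature.GENDER:
                assert res.feature_coverage[f] == pytest.approx(100.0, abs=1e-6)

    def test_toy_cohort_matches_hand_composition(self):
        """trial genders {M,M,F} vs target {M,F}: JSD and coverage by hand."""
        trial = [make_record(f"U{i}", gender=g) for i, g in enumerate(["Male", "Male", "Female"])]
        target = [make_record(f"V{i}", gender=g) for i, g in enumerate(["Male", "Female"])]
        res = score_cohort(trial, target)
        expected_jsd = brute_force_jsd([1 / 3, 2 / 3], [0.5, 0.5])
        assert res.feature_coverage[Feature.GENDER] == pytest.approx(
            (1 - expected_jsd) * 100, abs=1e-6
        )
        # all other features identical and complete
        expected_overall = aggregate(
            {f: 100.0 for f in Feature} | {Feature.GENDER: (1 - expected_jsd) * 100}
        )
        assert res.coverage_overall == pytest.approx(expected_overall, abs=1e-6)
        assert res.suitability == pytest.approx(
            0.6 * expected_overall + 0.4 * 100.0, abs=1e-6
        )

    def test_completeness_exact_at_zero_missingness(self, complete_cohort, target_cohort):
        res = score_cohort(complete_cohort, target_cohort)
        for f in Feature:
            assert res.feature_completeness[f] == 100.0

    def test_renormalisation_records_excluded_feature(self, target_cohort):
        trial = [make_record(f"W{i}", religion=None) for i in range(4)]
        res = score_cohort(trial, target_cohort, renormalise_on_missing_feature=True)
        assert res.excluded_features == (Feature.RELIGION,)
        with pytest.raises(NoValidDataError):
            score_cohort(trial, target_cohort)
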