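import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sltplan import (
    MetricConfig,
    coincidence_from_vectors,
    coincidence_percent,
    level1_distance,
    level2_distance,
    mean_manhattan,
    scale_factor,
)
from sltplan.model import CognitiveRecord

binary_vec = st.lists(st.integers(min_value=0, max_value=1), min_size=1, max_size=30)


def _paired(draw_len=st.integers(min_value=1, max_value=30)):
    return draw_len.flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 1), min_size=n, max_size=n),
            st.lists(st.integers(0, 1), min_size=n, max_size=n),
        )
    )


class TestMeanManhattan:
    def test_identity_and_extremes(self):
        assert mean_manhattan([1, 0, 1], [1, 0, 1]) == 0.0
        assert mean_manhattan([0, 1, 0, 1, 0], [1, 0, 1, 0, 1]) == 1.0
        x = [0] * 10
        y = [0] * 9 + [1]
        assert mean_manhattan(x, y) == pytest.approx(0.1)

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mean_manhattan([0, 1], [0, 1, 0])
        with pytest.raises(ValueError, match="0/1"):
            mean_manhattan([0, 2], [0, 1])

    @given(_paired())
    @settings(max_examples=300, deadline=None)
    def test_symmetry_and_bounds(self, pair):
        x, y = pair
        d = mean_manhattan(x, y)
        assert d == mean_manhattan(y, x)
        assert 0.0 <= d <= 1.0
        assert (d == 0.0) == (x == y)

    @given(
        st.integers(min_value=1, max_value=20).flatmap(
            lambda n: st.tuples(
                *[st.lists(st.integers(0, 1), min_size=n, max_size=n) for _ in range(3)]
            )
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_triangle_inequality(self, triple):
        x, y, z = triple
        assert mean_manhattan(x, z) <= mean_manhattan(x, y) + mean_manhattan(y, z) + 1e-12


class TestScaleFactor:
    def _rec(self, *ages):
        return CognitiveRecord(
            cognitive_age=ages[0],
            language_gap=ages[1],
            expressive_language_age=ages[2],
            receptive_language_age=ages[3],
        )

    def test_identical_records_zero(self):
        r = self._rec(60, 24, 48, 56)
        assert scale_factor(r, r, MetricConfig()) == 0.0

    def test_single_full_norm_difference(self):
        r1 = self._rec(60, 24, 48, 56)
        r2 = self._rec(60 + 216, 24, 48, 56)
        assert scale_factor(r1, r2, MetricConfig(scale_weight=1.0)) == pytest.approx(0.25)

    def test_linear_in_lambda_and_capped(self):
        r1 = self._rec(0, 0, 0, 0)
        r2 = self._rec(500, 0, 0, 0)  # beyond the cap
        one = scale_factor(r1, r2, MetricConfig(scale_weight=1.0))
        two = scale_factor(r1, r2, MetricConfig(scale_weight=2.0))
        assert two == pytest.approx(2 * one)
        assert one == pytest.approx(0.25)  # capped at age_norm


class TestCaseLevelMetrics:
    def test_identical_cases_distance_zero(self, small_cohort, catalogue):
        _, cases, _ = small_cohort
        c = cases[0]
        cfg = MetricConfig()
        for area in catalogue.area_names:
            assert level1_distance(c, c, area, catalogue) == 0.0
            assert level2_distance(c, c, area, catalogue, cfg) == 0.0
            assert coincidence_percent(c, c, area, catalogue) == 100.0

    def test_level1_counts_only_indexed_features(self, small_cohort, catalogue):
        _, cases, _ = small_cohort
        a, b = cases[0], cases[1]
        area = catalogue.area_names[0]
        idx = set(catalogue.area(area).features_mr)
        # flipping every out-of-set feature leaves the distance unchanged
        base = level1_distance(a, b, area, catalogue)
        mutated = b.model_copy(deep=True)
        for i in range(len(mutated.medical.features)):
            if i not in idx:
                mutated.medical.features[i] = 1 - mutated.medical.features[i]
        assert level1_distance(a, mutated, area, catalogue) == base

    def test_level1_fraction(self, small_cohort, catalogue):
        _, cases, _ = small_cohort
        area = catalogue.area_names[0]
        idx = catalogue.area(area).features_mr
        a = cases[0]
        b = a.model_copy(deep=True)
        b.medical.features[idx[0]] = 1 - b.medical.features[idx[0]]
        assert level1_distance(a, b, area, catalogue) == pytest.approx(1 / len(idx))

    def test_level2_decomposes(self, small_cohort, catalogue):
        _, cases, _ = small_cohort
        cfg = MetricConfig(scale_weight=1.0)
        a = cases[0]
        # same evaluation, one cognitive age off by exactly age_norm
        b = a.model_copy(deep=True)
        b.cognitive.cognitive_age += cfg.age_norm_months
        area = catalogue.area_names[-1]
        assert level2_distance(a, b, area, catalogue, cfg) == pytest.approx(0.25)
        # same ages, one evaluation dimension flipped in a 10-dim area
        c = a.model_copy(deep=True)
        c.evaluation.areas[area][0] = 1 - c.evaluation.areas[area][0]
        n = len(catalogue.area(area).dimensions)
        assert level2_distance(a, c, area, catalogue, cfg) == pytest.approx(1 / n)
        # the binary summand is a lower bound for level-2
        assert level2_distance(a, b, area, catalogue, cfg) >= 0.0

    def test_unknown_area_raises(self, small_cohort, catalogue):
        _, cases, _ = small_cohort
        with pytest.raises(KeyError):
            level1_distance(cases[0], cases[1], "swallowing", catalogue)


class TestCoincidence:
    def test_full_agreement_on_five_hearing_features(self):
        v = [1, 0, 1, 1, 0]
        assert coincidence_from_vectors(v, v) == 100.0

    def test_one_of_ten_disagreement(self):
        x = [1] * 10
        y = [1] * 9 + [0]
        assert coincidence_from_vectors(x, y) == pytest.approx(90.0)

    def test_three_of_ten_disagreement(self):
        x = [1] * 10
        y = [0, 0, 0] + [1] * 7
        assert coincidence_from_vectors(x, y) == pytest.approx(70.0)

    def test_case_level_ignores_scale_factor(self, small_cohort, catalogue):
        _, cases, _ = small_cohort
        a = cases[0]
        b = a.model_copy(deep=True)
        b.cognitive.cognitive_age += 100  # ages differ, evaluations identical
        for area in catalogue.area_names:
            assert coincidence_percent(a, b, area, catalogue) == 100.0

    @given(_paired())
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, pair):
        x, y = pair
        c = coincidence_from_vectors(x, y)
        assert 0.0 <= c <= 100.0
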