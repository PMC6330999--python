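"""Membership construction, inference, defuzzification and rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homeoconf.features import PairFeatures
from homeoconf.fuzzy import (
    GenomeStats,
    MembershipClass,
    Universe,
    ValidationError,
    build_model,
    centroid_defuzzify,
    evaluate_rules,
    fuzzify,
    genome_stats,
    infer_confidence,
    membership_degree,
    scale_scores,
)
from homeoconf.rules import RuleSet


def feat(syn, dist, cn):
    return PairFeatures(synteny_score=syn, distance=dist, total_copy_nr=cn)


STATS = GenomeStats(distance_max=2.0, copynr_median=2.0, copynr_max=20)


@pytest.fixture(scope="module")
def model():
    return build_model(STATS)


class TestUniverse:
    def test_grid_inclusive_of_bounds(self):
        u = Universe(0.0, 100.0, 1.0)
        grid = u.grid
        assert grid[0] == 0.0 and grid[-1] == 100.0 and len(grid) == 101

    def test_hi_appended_when_not_multiple_of_step(self):
        grid = Universe(0.0, 0.25, 0.1).grid
        assert grid[-1] == pytest.approx(0.25)
        assert grid[-2] == pytest.approx(0.2)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValidationError):
            Universe(1.0, 1.0, 0.1)


class TestGenomeStats:
    def test_summary_values(self):
        feats = [feat(0.5, d, c) for d, c in [(0.1, 2), (0.5, 2), (2.0, 10)]]
        s = genome_stats(feats)
        assert (s.distance_max, s.copynr_max) == (2.0, 10)

    def test_even_median_is_mean_of_middle_two(self):
        feats = [feat(0.5, 0.1, c) for c in (2, 2, 4, 10)]
        assert genome_stats(feats).copynr_median == 3.0

    def test_single_pair(self):
        s = genome_stats([feat(1.0, 0.3, 2)])
        assert (s.distance_max, s.copynr_median, s.copynr_max) == (0.3, 2.0, 2)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            genome_stats([])


class TestBuildModel:
    def test_distance_classes_scale_with_maximum(self, model):
        d = model.variables["distance"]
        assert (d.cls("low").center, d.cls("low").sd) == (0.0, 0.2)
        assert (d.cls("med").center, d.cls("med").sd) == (0.5, 0.2)
        assert (d.cls("high").center, d.cls("high").sd) == (2.0, 0.8)

    def test_copynr_classes_scale_with_median_and_max(self, model):
        c = model.variables["copynr"]
        assert (c.cls("low").center, c.cls("low").sd) == (2.0, 2.0)
        assert (c.cls("med").center, c.cls("med").sd) == (8.0, 3.0)
        assert (c.cls("high").center, c.cls("high").sd) == (20.0, 8.0)

    def test_synteny_classes_are_static(self, model):
        s = model.variables["synteny"]
        assert (s.cls("med").center, s.cls("med").sd) == (0.3, 0.15)
        assert (s.cls("high").center, s.cls("high").sd) == (1.0, 0.4)

    def test_confidence_output_five_classes_on_0_100(self, model):
        conf = model.confidence
        assert conf.universe.hi == 100.0
        assert [c.label for c in conf.classes] == [
            "very low", "low", "med", "high", "very high",
        ]
        assert conf.cls("very high").center == 100.0

    def test_zero_distance_fallback_warns(self):
        with pytest.warns(UserWarning, match="distance_max"):
            m = build_model(GenomeStats(0.0, 2.0, 10))
        assert m.variables["distance"].universe.hi == 0.01

    def test_all_one_to_one_fallback_warns(self):
        with pytest.warns(UserWarning, match="one-to-one"):
            m = build_model(GenomeStats(1.0, 2.0, 2))
        c = m.variables["copynr"]
        assert c.universe.hi == 3.0
        assert (c.cls("high").center, c.cls("high").sd) == (3.0, 1.2)

    def test_identical_stats_give_identical_models(self):
        m1, m2 = build_model(STATS), build_model(STATS)
        assert m1.to_dict() == m2.to_dict()


class TestMembershipAndFuzzify:
    def test_gaussian_closed_forms(self):
        cls = MembershipClass("low", 10.0, 4.0)
        assert membership_degree(10.0, cls) == 1.0
        assert membership_degree(14.0, cls) == pytest.approx(math.exp(-0.5))
        assert membership_degree(22.0, cls) == pytest.approx(math.exp(-4.5))

    def test_midhigh_synteny_belongs_to_all_three_classes(self, model):
        deg = fuzzify(feat(0.6, 0.1, 2), model)
        low, med, high = (deg[("synteny", l)] for l in ("low", "med", "high"))
        assert 0 < low < med < high
        assert high < 1.0

    def test_synteny_at_med_center_peaks(self, model):
        deg = fuzzify(feat(0.3, 0.1, 2), model)
        assert deg[("synteny", "med")] == 1.0

    def test_out_of_universe_input_clipped(self, model):
        # distance beyond the fitted maximum behaves as the maximum
        over = fuzzify(feat(0.5, 5.0, 2), model)
        at_hi = fuzzify(feat(0.5, 2.0, 2), model)
        assert over == at_hi
        assert over[("distance", "high")] == 1.0

    def test_non_finite_feature_rejected(self, model):
        with pytest.raises(ValidationError):
            fuzzify(feat(float("nan"), 0.1, 2), model)


class TestEvaluateRules:
    def test_full_strength_rule_reproduces_class_curve(self, model):
        rs = RuleSet.from_mapping({"rules": [{"if": "synteny is med", "then": "med"}]})
        m = build_model(STATS, rs)
        deg = fuzzify(feat(0.3, 0.1, 2), m)  # med fires at exactly 1
        curve = evaluate_rules(deg, m)
        grid = m.confidence.universe.grid
        np.testing.assert_allclose(curve, m.confidence.cls("med").degree(grid))

    def test_aggregate_bounded_by_max_firing_strength(self, model):
        deg = fuzzify(feat(0.45, 0.8, 6), model)
        strengths = [r.firing_strength(deg) for r in model.ruleset]
        curve = evaluate_rules(deg, model)
        assert curve.max() <= max(strengths) + 1e-12

    def test_ideal_corner_dominated_by_very_high(self, model):
        deg = fuzzify(feat(1.0, 0.0, 2), model)
        curve = evaluate_rules(deg, model)
        grid = model.confidence.universe.grid
        # the very-high consequent fires at full strength, so the aggregate
        # equals 1 at the top of the scale and the centroid sits near it
        assert deg[("synteny", "high")] == 1.0
        assert curve[-1] == pytest.approx(1.0)
        assert centroid_defuzzify(curve, model.confidence.universe) > 80


class TestCentroid:
    def test_symmetric_curve_centroid_at_center(self):
        u = Universe(0.0, 100.0, 1.0)
        curve = MembershipClass("med", 70.0, 5.0).degree(u.grid)
        assert centroid_defuzzify(curve, u) == pytest.approx(70.0, abs=1e-6)

    def test_interior_gaussian_untruncated(self):
        u = Universe(0.0, 100.0, 1.0)
        curve = MembershipClass("low", 50.0, 10.0).degree(u.grid)
        assert centroid_defuzzify(curve, u) == pytest.approx(50.0, abs=1e-6)

    def test_boundary_gaussian_pulled_inward(self):
        # mass beyond 100 is cut off, so the centroid falls strictly below
        # the center: the reason raw cohort maxima sit near 80-90, not 100
        u = Universe(0.0, 100.0, 1.0)
        curve = MembershipClass("very high", 100.0, 10.0).degree(u.grid)
        c = centroid_defuzzify(curve, u)
        assert c < 100.0
        fine = np.linspace(0, 100, 100001)
        vals = np.exp(-((fine - 100.0) ** 2) / 200.0)
        oracle = np.trapezoid(fine * vals, fine) / np.trapezoid(vals, fine)
        # unit-step discretization gives full weight to the boundary point,
        # so the discrete centroid sits slightly above the integral
        assert c == pytest.approx(oracle, abs=0.5)

    def test_matches_finer_grid_integration_on_random_aggregates(self, model):
        # independent oracle: the same max-of-truncated-Gaussians curve
        # evaluated on a 10x finer grid and integrated
        rng = np.random.default_rng(2024)
        u = model.confidence.universe
        classes = model.confidence.classes
        coarse = u.grid
        fine = Universe(u.lo, u.hi, u.step / 10).grid
        for _ in range(100):
            strengths = rng.uniform(0.05, 1.0, size=len(classes))

            def aggregate(x):
                return np.max(
                    [np.minimum(c.degree(x), s) for c, s in zip(classes, strengths)],
                    axis=0,
                )

            value = centroid_defuzzify(aggregate(coarse), u)
            oracle = float(
                np.trapezoid(fine * aggregate(fine), fine)
                / np.trapezoid(aggregate(fine), fine)
            )
            assert value == pytest.approx(oracle, abs=0.5)

    def test_all_zero_curve_rejected(self):
        u = Universe(0.0, 100.0, 1.0)
        with pytest.raises(ValidationError):
            centroid_defuzzify(np.zeros(101), u)


class TestScaleScores:
    def test_fixed_min_linear_stretch(self):
        assert scale_scores([40.0, 60.0, 80.0]) == pytest.approx([40.0, 70.0, 100.0])

    def test_identity_when_max_already_100(self):
        assert scale_scores([100.0, 50.0]) == pytest.approx([100.0, 50.0])

    def test_constant_cohort_maps_to_100(self):
        assert scale_scores([73.0, 73.0, 73.0]) == [100.0, 100.0, 100.0]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            scale_scores([])

    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1, max_size=30
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scaling_properties(self, raw):
        scaled = scale_scores(raw)
        assert max(scaled) == pytest.approx(100.0)
        assert all(0 <= s <= 100 + 1e-9 for s in scaled)
        # monotone: relative order of scores is preserved
        by_raw = sorted(zip(raw, scaled))
        assert all(
            a[1] <= b[1] + 1e-9 for a, b in zip(by_raw, by_raw[1:])
        )
        # never shrinks a score when the maximum is below 100
        if max(raw) < 100:
            assert all(s >= r - 1e-9 for r, s in zip(raw, scaled))


class TestMonotonicity:
    def test_confidence_monotone_along_each_input(self, model):
        syn = np.linspace(0, 1, 21)
        dist = np.linspace(0, 2, 21)
        cn = np.linspace(2, 20, 21)
        cube = np.empty((21, 21, 21))
        for i, s in enumerate(syn):
            for j, d in enumerate(dist):
                for k, c in enumerate(cn):
                    cube[i, j, k] = infer_confidence(feat(s, d, c), model)
        assert np.diff(cube, axis=0).min() >= -1e-9   # non-decreasing in synteny
        assert np.diff(cube, axis=1).max() <= 1e-9    # non-increasing in distance
        assert np.diff(cube, axis=2).max() <= 1e-9    # non-increasing in copy nr
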