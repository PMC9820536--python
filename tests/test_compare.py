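import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emgait as eg
from emgait.errors import InsufficientDataError


def mann_whitney_p_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by exhaustive enumeration of all
    C(n_a+n_b, n_a) assignments of the pooled ranks (no ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1

    def u_stat(idx_a):
        r_a = ranks[list(idx_a)].sum()
        u_a = r_a - n_a * (n_a + 1) / 2
        return min(u_a, n_a * n_b - u_a)

    observed = u_stat(range(n_a))
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n_a + n_b), n_a):
        total += 1
        if u_stat(combo) <= observed + 1e-12:
            extreme += 1
    return extreme / total


class TestNormalityScreen:
    def test_normal_draws_mostly_pass(self):
        rng = np.random.default_rng(0)
        hits = sum(
            eg.normality_screen(rng.standard_normal(500)).p_value > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_heavy_tailed_draws_mostly_fail(self):
        rng = np.random.default_rng(1)
        hits = sum(
            eg.normality_screen(rng.standard_t(df=2, size=500)).p_value < 0.05
            for _ in range(100)
        )
        assert hits >= 90

    def test_small_sample_untestable(self):
        res = eg.normality_screen([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.untestable
        assert math.isnan(res.p_value)


class TestCompareGroups:
    def test_identical_groups_degenerate(self):
        data = eg.GroupDataset("r", [0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert eg.compare_groups(data, "mann_whitney").p_value == 1.0

    def test_pooled_t_hand_computation(self):
        # a={1,2,3}, b={2,3,4}: pooled variance 1, se=sqrt(2/3), t=-sqrt(3/2)
        res = eg.compare_groups(eg.GroupDataset("x", [1, 2, 3], [2, 3, 4]), "student_t")
        t_hand = -1.0 / math.sqrt(2.0 / 3.0)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        from scipy import stats

        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t_hand), df=4), rel=1e-12)

    def test_mann_whitney_exact_matches_enumeration(self):
        a = [0.9, 0.8, 0.85, 0.95, 0.9001]
        b = [0.3, 0.4, 0.35, 0.2, 0.5, 0.45, 0.3001]
        res = eg.compare_groups(eg.GroupDataset("r", a, b), "mann_whitney")
        assert res.p_value == pytest.approx(mann_whitney_p_enumeration(a, b), abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        n_a=st.integers(2, 6), n_b=st.integers(2, 6), seed=st.integers(0, 10_000)
    )
    def test_exact_path_equals_enumeration_all_small_n(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, n_a)
        b = rng.uniform(0, 1, n_b)
        res = eg.compare_groups(eg.GroupDataset("r", a, b), "mann_whitney")
        assert res.p_value == pytest.approx(mann_whitney_p_enumeration(a, b), abs=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_label_swap_flips_direction_keeps_p(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 0.3, 6)
        b = rng.normal(1.3, 0.3, 7)
        r1 = eg.compare_groups(eg.GroupDataset("x", a, b), "student_t")
        r2 = eg.compare_groups(eg.GroupDataset("x", b, a), "student_t")
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.effect_direction == -r2.effect_direction


class TestRatioVsUnity:
    def test_all_unity_ratios(self):
        res = eg.ratio_vs_unity(eg.RatioDataset("amp", [1.0, 1.0, 1.0]))
        assert res.p_value == 1.0

    def test_hand_computed_one_sample_t(self):
        ratios = [0.5, 0.6, 0.4, 0.5, 0.55]
        mean = np.mean(ratios)
        sd = np.std(ratios, ddof=1)
        t_hand = (mean - 1.0) / (sd / math.sqrt(5))
        res = eg.ratio_vs_unity(eg.RatioDataset("amp", ratios))
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.effect_direction == -1

    def test_zero_variance_off_unity(self):
        res = eg.ratio_vs_unity(eg.RatioDataset("amp", [0.5, 0.5, 0.5]))
        assert res.p_value == 0.0
        assert "zero-variance" in res.flags

    def test_single_ratio_insufficient(self):
        with pytest.raises(InsufficientDataError):
            eg.ratio_vs_unity(eg.RatioDataset("amp", [0.5]))


class TestCompareCv:
    def test_identical_cv_lists_degenerate(self):
        data = eg.GroupDataset("cv", [0.2, 0.2], [0.2, 0.2])
        assert eg.compare_cv(data).p_value == 1.0

    def test_minimal_groups_compute(self):
        res = eg.compare_cv(eg.GroupDataset("cv", [0.1, 0.2], [0.3, 0.4]))
        assert 0.0 <= res.p_value <= 1.0

    def test_jitter_contrast_power(self):
        """Cohorts generated with low vs high cycle jitter separate on CV."""
        detected = 0
        for seed in range(10):
            low = [
                _cycle_cv(eg.treated_config(seed=seed, cycle_jitter_sd=0.05), i)
                for i in range(4)
            ]
            high = [
                _cycle_cv(eg.treated_config(seed=seed + 500, cycle_jitter_sd=0.20), i)
                for i in range(4)
            ]
            res = eg.compare_cv(eg.GroupDataset("cv", low, high))
            if res.p_value < 0.05 and res.effect_direction < 0:
                detected += 1
        assert detected >= 8


def _cycle_cv(cfg, animal_index):
    analysis = eg.analyze_recording(
        eg.generate_animal(cfg, animal_index), eg.PipelineConfig(bandpass_enabled=False)
    )
    return analysis.summaries[("Sol-L", "cycle_duration")].cv
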