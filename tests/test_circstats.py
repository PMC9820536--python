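import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pingouin import circ_r, circ_rayleigh
from scipy import special

import emgait as eg
from emgait.circstats import moore_critical_value
from emgait.errors import DataError, InsufficientDataError
from emgait.io import ChannelLabel


def _train(onsets, dur=0.1, channel="Sol-L"):
    bursts = [eg.Burst(o, o + dur, 1.0, o + dur / 2) for o in onsets]
    return eg.BurstTrain(ChannelLabel.parse(channel), bursts)


def _episode(start, end):
    return eg.Episode(start=start, end=end, kind="rhythmic", n_bursts_reference=10)


class TestOnsetPhases:
    def test_half_cycle_alternation(self):
        ps = eg.onset_phases(
            _train([0.0, 1.0, 2.0]), _train([0.5, 1.5], channel="Sol-R"), _episode(0.0, 2.5)
        )
        np.testing.assert_allclose(ps.phases, [180.0, 180.0])

    def test_synchrony_is_zero_phase(self):
        ps = eg.onset_phases(
            _train([0.0, 1.0, 2.0]), _train([0.0, 1.0], channel="Sol-R"), _episode(0.0, 2.5)
        )
        np.testing.assert_allclose(ps.phases, [0.0, 0.0])

    def test_quarter_cycle(self):
        ps = eg.onset_phases(
            _train([0.0, 1.0]), _train([0.25], channel="TA-L"), _episode(0.0, 1.5)
        )
        np.testing.assert_allclose(ps.phases, [90.0])

    def test_multiple_onsets_use_first_and_flag(self):
        ps = eg.onset_phases(
            _train([0.0, 1.0]), _train([0.25, 0.5], channel="TA-L", dur=0.05), _episode(0.0, 1.5)
        )
        np.testing.assert_allclose(ps.phases, [90.0])
        assert ps.multiplicity_flag

    def test_empty_cycles_skipped(self):
        ps = eg.onset_phases(
            _train([0.0, 1.0, 2.0, 3.0]), _train([2.5], channel="Sol-R"), _episode(0.0, 3.5)
        )
        assert len(ps) == 1


class TestMeanVector:
    def test_identical_angles(self):
        res = eg.mean_vector(np.full(10, 90.0))
        assert res.r == pytest.approx(1.0)
        assert res.mean_angle == pytest.approx(90.0)
        assert res.coordinated

    def test_symmetric_cancellation(self):
        res = eg.mean_vector([0.0, 90.0, 180.0, 270.0])
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            eg.mean_vector([])

    def test_against_pingouin_oracle(self):
        """r and the Rayleigh p must match an independent implementation."""
        rng = np.random.default_rng(123)
        for _ in range(10):
            deg = np.rad2deg(rng.vonmises(np.pi, 2.0, 25)) % 360.0
            res = eg.mean_vector(deg)
            rad = np.deg2rad(deg)
            assert res.r == pytest.approx(float(circ_r(rad)), abs=1e-12)
            _, p_ref = circ_rayleigh(rad)
            assert res.rayleigh_p == pytest.approx(p_ref, abs=1e-6)

    def test_critical_r_solves_rayleigh_p(self):
        for n in (8, 12, 20, 40):
            cr = eg.critical_r(n, alpha=0.05)
            assert eg.rayleigh_p(n, cr) == pytest.approx(0.05, rel=1e-9)
            assert eg.rayleigh_p(n, cr + 0.01) < 0.05 < eg.rayleigh_p(n, cr - 0.01)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5000), shift=st.floats(0.0, 360.0))
    def test_rotation_equivariance(self, seed, shift):
        """Adding a constant rotates the mean angle and leaves r and p fixed."""
        rng = np.random.default_rng(seed)
        deg = np.rad2deg(rng.vonmises(1.0, 3.0, 15)) % 360.0
        a = eg.mean_vector(deg)
        b = eg.mean_vector((deg + shift) % 360.0)
        assert b.r == pytest.approx(a.r, abs=1e-9)
        assert b.rayleigh_p == pytest.approx(a.rayleigh_p, abs=1e-9)
        diff = (b.mean_angle - a.mean_angle - shift) % 360.0
        assert min(diff, 360.0 - diff) < 1e-6


class TestWatsonU2:
    def test_identical_samples_not_rejected(self):
        a = np.array([10.0, 50.0, 120.0, 200.0, 280.0, 340.0])
        res = eg.watson_u2(a, a, method="permutation", n_permutations=999, seed=5)
        assert res.p_value > 0.9

    def test_opposed_concentrations_rejected(self):
        rng = np.random.default_rng(17)
        a = np.rad2deg(rng.vonmises(0.0, 20.0, 20)) % 360.0
        b = np.rad2deg(rng.vonmises(np.pi, 20.0, 20)) % 360.0
        res = eg.watson_u2(a, b, method="permutation", n_permutations=1999, seed=5)
        assert res.p_value < 0.01

    def test_asymptotic_close_to_permutation(self):
        rng = np.random.default_rng(29)
        a = np.rad2deg(rng.vonmises(0.0, 1.0, 30)) % 360.0
        b = np.rad2deg(rng.vonmises(0.7, 1.0, 30)) % 360.0
        p_asym = eg.watson_u2(a, b, method="asymptotic").p_value
        p_perm = eg.watson_u2(a, b, method="permutation", n_permutations=9999, seed=0).p_value
        if 0.01 <= p_asym <= 0.5:
            assert abs(p_asym - p_perm) < 0.02

    def test_common_rotation_invariance(self):
        rng = np.random.default_rng(31)
        a = rng.uniform(0, 360, 15)
        b = rng.uniform(0, 360, 12)
        u0 = eg.watson_u2(a, b).statistic
        # rotation moves mass across 0/360 but U2 is a circular statistic
        for shift in (45.0, 123.4, 270.0):
            u1 = eg.watson_u2((a + shift) % 360, (b + shift) % 360).statistic
            assert u1 == pytest.approx(u0, abs=5e-3)

    def test_undersized_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            eg.watson_u2([0.0, 10.0, 20.0], [5.0, 15.0, 25.0, 35.0])


class TestMoorePaired:
    def test_null_identity_pairs(self):
        pairs = [(a, a) for a in [10.0, 80.0, 150.0, 220.0, 290.0, 355.0]]
        res = eg.moore_paired(pairs, seed=3)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value > 0.99

    def test_consistent_shift_detected(self):
        # pre-drug phases concentrated near 180 deg; post shifted by +90
        rng = np.random.default_rng(41)
        pre = 180.0 + 5.0 * rng.standard_normal(10)
        pairs = np.column_stack([pre, pre + 90.0])
        res = eg.moore_paired(pairs, n_permutations=9999, seed=3)
        assert res.p_value < 0.05

    def test_four_pairs_insufficient(self):
        with pytest.raises(InsufficientDataError):
            eg.moore_paired([(0.0, 1.0)] * 4)

    def test_non_finite_angle_rejected(self):
        with pytest.raises(DataError):
            eg.moore_paired([(0.0, np.nan)] + [(10.0, 20.0)] * 5)

    def test_table_consistent_with_monte_carlo_null(self):
        """The embedded critical value sits at the null 95th percentile."""
        n = 10
        rng = np.random.default_rng(7)
        ranks = np.arange(1, n + 1)
        th = rng.uniform(0, 2 * np.pi, size=(200_000, n))
        rstar = np.hypot((ranks * np.cos(th)).sum(1), (ranks * np.sin(th)).sum(1)) / n**1.5
        crit = moore_critical_value(n, 0.05)
        frac = np.mean(rstar >= crit)
        assert frac == pytest.approx(0.05, abs=0.003)


class TestCoordinationReport:
    def test_von_mises_cohort_recovery(self):
        """Generative kappa maps to r via I1(kappa)/I0(kappa)."""
        kappa = 8.0
        r_theory = special.i1(kappa) / special.i0(kappa)
        cfg = eg.treated_config(seed=2, phase_kappa=kappa)
        rec = eg.generate_animal(cfg, 0)
        results = eg.coordination_report(rec)
        inter = [r for r in results if r.pairing == "interlimb"]
        assert len(inter) == 1
        assert abs(((inter[0].mean_angle - 180.0 + 180.0) % 360.0) - 180.0) < 10.0
        assert inter[0].r == pytest.approx(r_theory, abs=0.05)

    def test_uncoordinated_cohort_flagged(self):
        """Uniform phase jitter leaves most animals below the cR criterion.

        The rate is asserted at the cohort level: burst merging censors
        phases where test bursts abut, so single animals occasionally clear
        cR even with no generative coupling.
        """
        uncoordinated = total = 0
        for seed in range(12):
            cfg = eg.control_config(seed=seed, phase_kappa=0.0)
            rec = eg.generate_animal(cfg, 1)
            for r in eg.coordination_report(rec):
                if r.pairing == "interlimb":
                    total += 1
                    uncoordinated += not r.coordinated
        assert uncoordinated >= 0.6 * total

    def test_missing_channels_usage_error(self):
        cfg = eg.treated_config(seed=0, duration=12.0)
        rec = eg.generate_animal(cfg, 0)
        import dataclasses

        sub = dataclasses.replace(
            rec,
            channels=rec.channels[:2],
            signal=rec.signal[:, :2],
        )
        with pytest.raises(eg.UsageError):
            eg.coordination_report(sub)
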