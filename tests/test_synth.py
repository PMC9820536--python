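import dataclasses

import numpy as np
import pytest

import emgait as eg
from emgait.errors import ConfigError


class TestGenerateAnimal:
    def test_same_seed_is_bit_identical(self):
        cfg = eg.treated_config(seed=9)
        a = eg.generate_animal(cfg, 3)
        b = eg.generate_animal(cfg, 3)
        assert np.array_equal(a.signal, b.signal)
        assert a.meta == b.meta

    def test_distinct_animals_differ(self):
        cfg = eg.treated_config(seed=9)
        a = eg.generate_animal(cfg, 0)
        b = eg.generate_animal(cfg, 1)
        assert not np.array_equal(a.signal, b.signal)

    def test_recording_invariants_hold(self):
        rec = eg.generate_animal(eg.control_config(seed=1), 2)
        assert np.all(np.isfinite(rec.signal))
        assert rec.channel_names == ["Sol-L", "Sol-R", "TA-L", "TA-R"]
        assert rec.duration == pytest.approx(20.0)

    def test_noise_free_square_bursts_exact_amplitude(self):
        cfg = eg.treated_config(
            seed=0, carrier_band=None, noise_sd=0.0, amp_jitter_cv=0.0,
            phase_kappa=np.inf, cycle_jitter_sd=0.0,
        )
        rec = eg.generate_animal(cfg, 0)
        env = eg.integrate(rec, "Sol-L", 0.005)
        train = eg.detect_bursts(env)
        assert len(train) >= 10
        for b in train.bursts:
            assert b.peak_amplitude == pytest.approx(cfg.sol_amp)

    def test_noise_free_alternation_is_exact(self):
        cfg = eg.treated_config(
            seed=0, carrier_band=None, noise_sd=0.0, amp_jitter_cv=0.0,
            phase_kappa=np.inf, cycle_jitter_sd=0.0,
        )
        rec = eg.generate_animal(cfg, 0)
        analysis = eg.analyze_recording(rec, eg.PipelineConfig(bandpass_enabled=False))
        inter = analysis.coordination_for("interlimb")
        assert inter.mean_angle == pytest.approx(180.0, abs=1.8)
        assert inter.r > 0.999

    def test_invalid_duty_rejected(self):
        with pytest.raises(ConfigError):
            eg.treated_config(sol_duty=1.2)

    def test_ground_truth_events_recorded(self):
        rec = eg.generate_animal(eg.treated_config(seed=3), 0)
        events = rec.meta["generator"]["events"]
        assert set(events) == {"Sol-L", "Sol-R", "TA-L", "TA-R"}
        onsets = [e[0] for e in events["Sol-L"]]
        assert onsets == sorted(onsets)


class TestGenerateCohort:
    def test_default_design_sizes(self):
        recs = eg.generate_cohort()
        groups = [r.group for r in recs]
        assert groups.count("TTx2EB") == 5
        assert groups.count("TTnoEB") == 7
        assert len({r.animal_id for r in recs}) == 12

    def test_single_animal_cohort_propagates_insufficient_data(self):
        recs = eg.generate_cohort(
            eg.treated_config(n_animals=1), eg.control_config(n_animals=1)
        )
        metrics, _ = eg.analyze_cohort(recs)
        cv = metrics[(metrics.muscle == "Sol-L") & (metrics.parameter == "cycle_duration")]
        with pytest.raises(eg.InsufficientDataError):
            eg.GroupDataset(
                "cv",
                cv[cv.group == "TTx2EB"].cv.values,
                cv[cv.group == "TTnoEB"].cv.values,
            )


class TestApplyDrugEffect:
    def test_identity_transform_matches_generative_stats(self):
        cfg = eg.treated_config(seed=5)
        null_drug = eg.DrugEffectConfig(
            amp_scale_sol=1.0, amp_scale_ta=1.0, sol_duration_scale=1.0,
            ta_duration_scale=1.0, phase_kappa_post=cfg.phase_kappa,
        )
        pre, post = eg.apply_drug_effect(cfg, null_drug, 0)
        assert pre.condition == "pre_drug" and post.condition == "post_drug"
        g_pre = pre.meta["generator"]["config"]
        g_post = post.meta["generator"]["config"]
        for key in ("sol_amp", "ta_amp", "sol_duty", "ta_duty", "phase_kappa"):
            assert g_pre[key] == g_post[key]
        assert not np.array_equal(pre.signal, post.signal)  # independent realization

    def test_default_transform_scales_config(self):
        cfg = eg.treated_config(seed=5)
        drug = eg.DrugEffectConfig()
        _, post = eg.apply_drug_effect(cfg, drug, 0)
        g = post.meta["generator"]["config"]
        assert g["sol_amp"] == pytest.approx(cfg.sol_amp * drug.amp_scale_sol)
        assert g["ta_duty"] == pytest.approx(cfg.ta_duty * drug.ta_duration_scale)
        assert g["phase_kappa"] == pytest.approx(drug.phase_kappa_post)

    def test_overlong_scaled_ta_duty_rejected(self):
        cfg = eg.treated_config(seed=0, ta_duty=0.5)
        with pytest.raises(ConfigError):
            eg.apply_drug_effect(cfg, eg.DrugEffectConfig(ta_duration_scale=2.2), 0)
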