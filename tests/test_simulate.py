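"""Synthetic cohort generator: structure, determinism, variability model."""

import numpy as np
import pytest

from gaitphase.kinematics import angular_velocity, detect_heel_strikes
from gaitphase.simulate import (SPEED_CONDITIONS, SubjectProfile,
                                VariabilityModel, apply_variability,
                                generate_cohort, generate_trial,
                                sample_subject_profile, synthetic_grf,
                                thigh_profile, torso_profile)


class TestProfiles:
    def test_thigh_periodicity(self):
        p = SubjectProfile("S")
        assert thigh_profile(0.0, p) == pytest.approx(thigh_profile(100.0, p))

    def test_zero_harmonics_constant(self):
        p = SubjectProfile("S", thigh_harmonics=())
        phi = np.linspace(0, 100, 57)
        assert np.allclose(thigh_profile(phi, p), 0.0)

    def test_single_harmonic_peak_to_peak(self):
        p = SubjectProfile("S", thigh_harmonics=((12.5, 0.7),))
        phi = np.linspace(0, 100, 20001)
        vals = thigh_profile(phi, p)
        assert np.max(vals) - np.min(vals) == pytest.approx(25.0, abs=1e-4)

    def test_torso_zero_amp_constant(self):
        p = SubjectProfile("S", torso_osc_amp_deg=0.0, torso_lean_deg=4.2)
        assert torso_profile(33.3, p) == pytest.approx(4.2)

    def test_torso_half_cycle_symmetry(self):
        p = SubjectProfile("S", torso_osc_phase_rad=0.3)
        phi = np.linspace(0, 50, 301)
        assert np.allclose(torso_profile(phi, p), torso_profile(phi + 50, p),
                           atol=1e-12)

    def test_torso_cycle_mean_is_lean(self):
        p = SubjectProfile("S", torso_lean_deg=6.5)
        from scipy.integrate import quad
        mean, _ = quad(lambda x: torso_profile(x, p), 0, 100, limit=200)
        assert mean / 100 == pytest.approx(6.5, abs=1e-9)

    def test_torso_two_maxima_per_cycle(self):
        p = SubjectProfile("S")
        phi = np.linspace(0, 100, 10000, endpoint=False)
        v = torso_profile(phi, p)
        d = np.diff(v, append=v[:1])            # circular difference
        n_max = np.sum((d > 0) & (np.roll(d, -1) <= 0))
        assert n_max == 2

    def test_phi_out_of_range(self):
        p = SubjectProfile("S")
        with pytest.raises(ValueError):
            thigh_profile(100.5, p)
        with pytest.raises(ValueError):
            torso_profile(-1.0, p)


class TestVariabilityModel:
    def test_default_invariants_hold(self):
        VariabilityModel()
        VariabilityModel.informative_torso()
        VariabilityModel.zero()

    def test_nonmonotone_torso_rejected(self):
        with pytest.raises(ValueError, match="strictly decrease"):
            VariabilityModel(torso_angle_mult={"C1": 1.0, "C2": 2.0, "C3": 3.0,
                                               "C4": 1.0, "C5": 1.0})

    def test_thigh_above_torso_rejected(self):
        with pytest.raises(ValueError, match="thigh"):
            VariabilityModel(thigh_mult={"C1": 9.0, "C2": 1.0, "C3": 1.0,
                                         "C4": 1.0, "C5": 1.0})


class TestGenerateCohort:
    def test_counts(self):
        cohort = generate_cohort(5, ["C2", "C3"], 2, seed=1)
        assert len(cohort) == 5 * 2 * 2

    def test_determinism(self):
        a = generate_cohort(3, ["C2"], 1, seed=7)
        b = generate_cohort(3, ["C2"], 1, seed=7)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.thigh_angle_deg, rb.thigh_angle_deg)
            assert np.array_equal(ra.torso_vel_dps, rb.torso_vel_dps)
            assert np.array_equal(ra.heel_strikes_s, rb.heel_strikes_s)

    def test_speed_in_condition_range(self):
        for rec in generate_cohort(8, ["C2"], 3, seed=3):
            assert 0.4 <= rec.nominal_speed_m_s <= 0.8
            assert SPEED_CONDITIONS[rec.condition].contains(rec.nominal_speed_m_s)

    def test_structure(self, small_cohort):
        for rec in small_cohort:
            assert rec.sampling_rate == 100.0
            assert len(rec.heel_strikes_s) >= 2
            assert len(rec.thigh_angle_deg) == len(rec.time_s)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            generate_cohort(0, ["C2"], 1)
        with pytest.raises(ValueError):
            generate_cohort(1, ["C2"], 0)

    def test_velocity_consistency_noise_free(self, clean_cohort):
        for rec in clean_cohort:
            assert np.allclose(
                rec.thigh_vel_dps,
                angular_velocity(rec.thigh_angle_deg, rec.sampling_rate))
            assert np.allclose(
                rec.torso_vel_dps,
                angular_velocity(rec.torso_angle_deg, rec.sampling_rate))


class TestApplyVariability:
    def test_zero_amplitudes_identity(self):
        rec = generate_cohort(1, ["C3"], 1,
                              variability=VariabilityModel.zero(), seed=5)[0]
        out = apply_variability(rec, VariabilityModel.zero(), seed=9)
        assert np.allclose(out.thigh_angle_deg, rec.thigh_angle_deg)
        assert np.allclose(out.torso_vel_dps, rec.torso_vel_dps)
        assert np.array_equal(out.heel_strikes_s, rec.heel_strikes_s)

    def test_same_seed_same_perturbation(self):
        rec = generate_cohort(1, ["C3"], 1,
                              variability=VariabilityModel.zero(), seed=5)[0]
        a = apply_variability(rec, VariabilityModel(), seed=3)
        b = apply_variability(rec, VariabilityModel(), seed=3)
        assert np.array_equal(a.torso_angle_deg, b.torso_angle_deg)

    def test_events_unchanged(self):
        rec = generate_cohort(1, ["C2"], 1, seed=5)[0]
        out = apply_variability(rec, VariabilityModel(), seed=1)
        assert np.array_equal(out.heel_strikes_s, rec.heel_strikes_s)
        assert np.array_equal(out.toe_offs_s, rec.toe_offs_s)

    def test_unknown_condition_rejected(self):
        rec = generate_cohort(1, ["C2"], 1, seed=5)[0]
        from dataclasses import replace
        bad = replace(rec, condition="C9")
        with pytest.raises(ValueError, match="C9"):
            apply_variability(bad, VariabilityModel(), seed=0)

    def test_slow_speed_torso_noisier(self):
        """C1 torso perturbation amplitude exceeds C3's (same base trial)."""
        profile = sample_subject_profile("S1", np.random.default_rng(0))
        v = VariabilityModel()
        devs = {}
        for cond in ("C1", "C3"):
            clean = generate_trial(profile, SPEED_CONDITIONS[cond],
                                   VariabilityModel.zero(), seed=11)
            noisy = apply_variability(clean, v, seed=13)
            devs[cond] = np.std(noisy.torso_angle_deg - clean.torso_angle_deg)
        assert devs["C1"] > devs["C3"]


class TestSyntheticGrf:
    def test_event_recovery_within_one_sample(self):
        rec = generate_cohort(1, ["C3"], 1, seed=21)[0]
        grf = synthetic_grf(rec.heel_strikes_s, rec.toe_offs_s,
                            rec.time_s[-1])
        detected = detect_heel_strikes(grf, threshold_n=20.0)
        matched = rec.heel_strikes_s[:len(rec.toe_offs_s)]
        assert len(detected) == len(matched)
        assert np.max(np.abs(detected - matched)) <= 1.0 / grf.sampling_rate
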