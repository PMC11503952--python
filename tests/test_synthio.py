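"""Generator contracts: determinism, task design constants, ground-truth
kinematics and the built-in latency-error coupling."""

import numpy as np
import pandas as pd
import pytest

from oculokit import synthio
from oculokit.synthio import GeneratorConfig, gen_antisaccade_trials, gen_cohort, \
    gen_prosaccade_trials, gen_pupil_trace, gen_subject_params

from conftest import make_subject


class TestSubjectParams:
    def test_zero_variance_population_collapses_to_means(self, noise_free_config, rng):
        for i in range(5):
            s = gen_subject_params(noise_free_config, "control", rng, f"c{i}")
            assert s.V_true == noise_free_config.V_group_mean
            assert s.gain == noise_free_config.amplitude_gain_mean

    def test_same_seed_same_params(self, small_config):
        draws = [
            gen_subject_params(small_config, "patient", np.random.default_rng(5), "p1")
            for _ in range(2)
        ]
        assert draws[0] == draws[1]

    def test_invalid_group_label_rejected(self, small_config, rng):
        with pytest.raises(ValueError, match="group"):
            gen_subject_params(small_config, "martian", rng, "x")

    def test_population_mean_recovered_at_large_n(self):
        cfg = GeneratorConfig(V_group_mean=130.0, V_group_sd=10.0)
        rng = np.random.default_rng(99)
        draws = np.array(
            [gen_subject_params(cfg, "control", rng, f"s{i}").V_true for i in range(10_000)]
        )
        assert abs(draws.mean() - 130.0) < 3 * 10.0 / np.sqrt(10_000)


class TestProsaccadeTrials:
    def test_noise_free_main_sequence_point(self, noise_free_config, rng):
        subj = make_subject(V_true=130.0, gain=1.0)
        trials, _ = gen_prosaccade_trials(subj, noise_free_config, "control", rng)
        five = trials[trials["target_eccentricity_deg"] == 5.0]
        assert np.allclose(five["amplitude_deg"], 5.0)
        assert np.allclose(five["peak_velocity_deg_s"], 130.0 * np.sqrt(5.0))

    def test_noise_free_trials_sit_exactly_on_sqrt_curve(self, noise_free_config, rng):
        subj = make_subject(V_true=130.0, gain=1.0)
        trials, _ = gen_prosaccade_trials(subj, noise_free_config, "control", rng)
        dev = trials["peak_velocity_deg_s"] - 130.0 * np.sqrt(trials["amplitude_deg"])
        assert np.abs(dev).max() < 1e-9

    def test_balanced_eccentricities(self, small_config, rng):
        trials, _ = gen_prosaccade_trials(make_subject(), small_config, "control", rng)
        counts = trials["target_eccentricity_deg"].value_counts()
        assert sorted(counts.index) == [-7.0, -5.0, -3.0, 3.0, 5.0, 7.0]
        assert (counts == 4).all()

    def test_latency_support_above_shift(self, small_config, rng):
        trials, _ = gen_prosaccade_trials(make_subject(), small_config, "control", rng)
        assert (trials["latency_ms"] > small_config.latency_shift).all()

    def test_indivisible_trial_count_rejected(self, rng):
        cfg = GeneratorConfig(trials_per_task=25)
        with pytest.raises(ValueError, match="divisible"):
            gen_prosaccade_trials(make_subject(), cfg, "control", rng)

    def test_profiles_integrate_to_amplitude(self, small_config, rng):
        trials, profiles = gen_prosaccade_trials(make_subject(), small_config, "control", rng)
        for trial_idx, grp in profiles.groupby("trial_index"):
            t_s = grp["t_norm"].to_numpy() * grp["sacc_duration_ms"].iloc[0] / 1000.0
            travelled = np.trapezoid(grp["velocity_deg_s"].to_numpy(), t_s)
            amp = trials.loc[trials["trial_index"] == trial_idx, "amplitude_deg"].iloc[0]
            assert abs(travelled - amp) / amp < 0.01

    def test_profile_peak_equals_drawn_peak_velocity(self, small_config, rng):
        trials, profiles = gen_prosaccade_trials(make_subject(), small_config, "control", rng)
        peaks = profiles.groupby("trial_index")["velocity_deg_s"].max()
        assert np.allclose(peaks.to_numpy(), trials.set_index("trial_index").loc[
            peaks.index, "peak_velocity_deg_s"].to_numpy())


class TestAntisaccadeTrials:
    def test_extreme_negative_propensity_gives_no_errors(self, small_config, rng):
        subj = make_subject(prop=-50.0)
        cfg = GeneratorConfig(n_patients=4, n_controls=4, urgency_coupling=0.0, seed=3)
        trials = gen_antisaccade_trials(subj, cfg, "control", rng)
        assert not trials["is_error"].any()

    def test_error_trials_are_faster_on_average(self):
        cfg = GeneratorConfig(trials_per_task=600, urgency_coupling=1.0, seed=21)
        rng = np.random.default_rng(21)
        blocks = [
            gen_antisaccade_trials(make_subject(prop=-0.5), cfg, "control", rng)
            for _ in range(9)
        ]
        trials = pd.concat(blocks)
        err = trials[trials["is_error"]]["latency_ms"].mean()
        corr = trials[~trials["is_error"]]["latency_ms"].mean()
        assert err < corr

    def test_errors_go_toward_target(self, small_config, rng):
        subj = make_subject(prop=3.0)  # error-prone
        trials = gen_antisaccade_trials(subj, small_config, "control", rng)
        err = trials[trials["is_error"]]
        disp = np.sign(err["end_x_deg"] - err["start_x_deg"])
        assert (disp == np.sign(err["target_eccentricity_deg"])).all()

    def test_same_seed_same_error_pattern(self, small_config):
        t1 = gen_antisaccade_trials(make_subject(), small_config, "control", np.random.default_rng(4))
        t2 = gen_antisaccade_trials(make_subject(), small_config, "control", np.random.default_rng(4))
        pd.testing.assert_frame_equal(t1, t2)


class TestPupilTrace:
    def test_clean_config_gives_constant_valid_trace(self, noise_free_config, rng):
        tr = gen_pupil_trace(make_subject(baseline=1500.0), noise_free_config, "control", rng, 20.0)
        assert tr.valid.all()
        assert np.allclose(tr.diameter, 1500.0)

    def test_three_minutes_at_500hz_is_90000_samples(self, small_config, rng):
        tr = gen_pupil_trace(make_subject(), small_config, "control", rng, 180.0)
        assert len(tr.diameter) == 90_000

    def test_drug_shift_is_additive(self, noise_free_config, rng):
        subj = make_subject()
        a = gen_pupil_trace(subj, noise_free_config, "atomoxetine", rng, 10.0)
        p = gen_pupil_trace(subj, noise_free_config, "placebo", rng, 10.0)
        shift = noise_free_config.drug_effect.pupil_shift_au
        assert np.isclose(a.diameter.mean() - p.diameter.mean(), shift)

    def test_blinks_are_flagged_invalid(self, rng):
        cfg = GeneratorConfig(blink_rate=40.0, seed=2)
        tr = gen_pupil_trace(make_subject(), cfg, "control", rng, 60.0)
        assert not tr.valid.all()
        assert (tr.diameter[~tr.valid] == 0).all()


class TestCohort:
    def test_default_cohort_has_63_sessions(self):
        cohort = gen_cohort(GeneratorConfig(seed=1), pupil_duration=5.0)
        assert len(cohort.sessions) == 19 * 2 + 25

    def test_patients_have_both_conditions_controls_one(self, small_config):
        cohort = gen_cohort(small_config, pupil_duration=5.0)
        by_subj = {}
        for s in cohort.sessions:
            by_subj.setdefault(s.subject_id, []).append(s.condition)
        for sid, conds in by_subj.items():
            if sid.startswith("pd"):
                assert sorted(conds) == ["atomoxetine", "placebo"]
            else:
                assert conds == ["control"]

    def test_visit_order_block_randomized(self):
        cohort = gen_cohort(GeneratorConfig(seed=1), pupil_duration=5.0)
        firsts = cohort.truth.loc[cohort.truth["group"] == "patient", "first_condition"]
        n_atx = (firsts == "atomoxetine").sum()
        assert {n_atx, 19 - n_atx} == {9, 10}

    def test_cohort_deterministic_under_seed(self, small_config):
        a = synthio.cohort_events(gen_cohort(small_config, pupil_duration=5.0))
        b = synthio.cohort_events(gen_cohort(small_config, pupil_duration=5.0))
        pd.testing.assert_frame_equal(a, b)

    def test_serialization_deterministic(self, small_config, tmp_path):
        for d in ("a", "b"):
            synthio.write_cohort(gen_cohort(small_config, pupil_duration=5.0), tmp_path / d)
        for name in ("events.tsv", "trials.tsv", "velocity_samples.tsv", "truth.tsv", "pupil.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_asymmetric_eccentricities_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            GeneratorConfig(eccentricities=(-3.0, 5.0)).validate()
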