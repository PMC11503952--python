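"""Primary-saccade gates, direction classification, the +/-2.5 SD
participant filter and error-rate accounting."""

import numpy as np
import pandas as pd
import pytest

from oculokit.saccparse import ParseParams, participant_outlier_filter, process_events, \
    select_primary, summarize_task
from oculokit.synthio import GeneratorConfig, gen_antisaccade_trials, gen_cohort, cohort_events

from conftest import make_subject


def make_events(rows, task="prosaccade", subject="s1", condition="placebo"):
    """rows: list of (trial, amp, lat, start_x, end_x, side)."""
    recs = []
    for trial, amp, lat, sx, ex, side in rows:
        recs.append(
            {
                "subject_id": subject,
                "group": "patient",
                "condition": condition,
                "visit_order": 1,
                "task": task,
                "trial_index": trial,
                "target_onset_ms": 1000.0,
                "target_side": side,
                "target_eccentricity_deg": 5.0 if side == "right" else -5.0,
                "sacc_onset_ms": 1000.0 + lat,
                "sacc_duration_ms": 30.0,
                "amplitude_deg": amp,
                "peak_velocity_deg_s": 130 * np.sqrt(amp),
                "start_x_deg": sx,
                "end_x_deg": ex,
            }
        )
    return pd.DataFrame(recs)


class TestSelectPrimary:
    def test_first_event_failing_amplitude_gate_is_skipped(self):
        ev = make_events([(0, 0.8, 120, 0.0, 0.7, "right"), (0, 4.2, 210, 0.0, 4.2, "right")])
        out = select_primary(ev)
        assert len(out) == 1 and out.loc[0, "valid"]
        assert out.loc[0, "amplitude_deg"] == 4.2

    def test_anticipatory_saccade_invalidates_trial(self):
        ev = make_events([(0, 5.0, 80, 0.0, 5.0, "right")])
        out = select_primary(ev)
        assert not out.loc[0, "valid"]
        assert out.loc[0, "removal_reason"] == "no_valid_saccade"

    @pytest.mark.parametrize("amp,lat,ok", [
        (1.5, 200.0, False),   # amplitude bounds are strict: ties excluded
        (10.0, 200.0, False),
        (1.6, 200.0, True),
        (5.0, 90.0, False),    # latency bounds are strict
        (5.0, 2500.0, False),
        (5.0, 200.0, True),
    ])
    def test_bounds_are_strict(self, amp, lat, ok):
        ev = make_events([(0, amp, lat, 0.0, amp, "right")])
        assert bool(select_primary(ev).loc[0, "valid"]) is ok

    def test_zero_displacement_is_ambiguous(self):
        ev = make_events([(0, 5.0, 200, 2.0, 2.0, "right")])
        out = select_primary(ev)
        assert not out.loc[0, "valid"]
        assert out.loc[0, "removal_reason"] == "ambiguous_direction"


class TestClassifyDirection:
    def test_antisaccade_toward_target_is_error(self):
        ev = make_events([(0, 4.1, 200, 0.0, 4.1, "right")], task="antisaccade")
        assert select_primary(ev).loc[0, "correct"] == False  # noqa: E712

    def test_prosaccade_toward_target_is_correct(self):
        ev = make_events([(0, 2.8, 200, 0.0, -2.8, "left")])
        assert select_primary(ev).loc[0, "correct"] == True  # noqa: E712

    def test_antisaccade_away_from_target_is_correct(self):
        ev = make_events([(0, 5.0, 200, 0.0, -5.0, "right")], task="antisaccade")
        assert select_primary(ev).loc[0, "correct"] == True  # noqa: E712

    def test_prosaccade_wrong_way_discarded_by_default(self):
        ev = make_events([(0, 5.0, 200, 0.0, -5.0, "right")])
        out = select_primary(ev)
        assert not out.loc[0, "valid"]
        assert out.loc[0, "removal_reason"] == "wrong_direction"

    def test_prosaccade_wrong_way_search_takes_later_toward_saccade(self):
        ev = make_events(
            [(0, 5.0, 200, 0.0, -5.0, "right"), (0, 4.0, 400, -5.0, -1.0, "right")]
        )
        out = select_primary(ev, ParseParams(prosaccade_wrong_way="search"))
        assert out.loc[0, "valid"] and out.loc[0, "latency_ms"] == 400


class TestOutlierFilter:
    def test_hand_computed_latency_outlier_removed(self):
        # latencies {200 x9, 2000}: mean 380, SD 569.2 -> only 2000 removed
        rows = [(i, 5.0, 200.0, 0.0, 5.0, "right") for i in range(9)]
        rows.append((9, 5.0, 2000.0, 0.0, 5.0, "right"))
        prim = select_primary(make_events(rows, task="antisaccade"))
        kept, log = participant_outlier_filter(prim)
        assert len(kept) == 9
        assert list(log["trial_index"]) == [9]
        assert log.loc[0, "removal_reason"] == "participant_outlier"

    def test_identical_values_nothing_removed(self):
        rows = [(i, 5.0, 200.0, 0.0, 5.0, "right") for i in range(10)]
        prim = select_primary(make_events(rows, task="antisaccade"))
        kept, log = participant_outlier_filter(prim)
        assert len(kept) == 10 and len(log) == 0

    def test_small_cells_flagged_not_filtered(self):
        rows = [(0, 5.0, 200.0, 0.0, 5.0, "right"), (1, 5.0, 900.0, 0.0, 5.0, "right")]
        prim = select_primary(make_events(rows, task="antisaccade"))
        kept, log = participant_outlier_filter(prim)
        assert len(kept) == 2 and len(log) == 0


class TestSummaries:
    def test_error_rate_denominator_excludes_removed(self):
        summary = summarize_task(
            pd.DataFrame(
                {
                    "subject_id": "s1", "condition": "placebo", "task": "antisaccade",
                    "trial_index": range(22), "correct": [False] * 5 + [True] * 17,
                    "latency_ms": 200.0, "amplitude_deg": 5.0,
                    "peak_velocity_deg_s": 290.0,
                }
            ),
            pd.DataFrame(
                {
                    "subject_id": ["s1"] * 2, "condition": ["placebo"] * 2,
                    "task": ["antisaccade"] * 2, "trial_index": [22, 23],
                    "removal_reason": ["participant_outlier"] * 2,
                }
            ),
            n_trials_total=24,
        )
        assert summary.loc[0, "n_completed"] == 22
        assert np.isclose(summary.loc[0, "error_rate"], 5 / 22)

    @pytest.mark.parametrize("n_err,expected", [(0, 0.0), (22, 1.0)])
    def test_error_rate_bounds(self, n_err, expected):
        prim = pd.DataFrame(
            {
                "subject_id": "s1", "condition": "placebo", "task": "antisaccade",
                "trial_index": range(22),
                "correct": [False] * n_err + [True] * (22 - n_err),
                "latency_ms": 200.0, "amplitude_deg": 5.0, "peak_velocity_deg_s": 290.0,
            }
        )
        log = pd.DataFrame(
            {
                "subject_id": ["s1"] * 2, "condition": ["placebo"] * 2,
                "task": ["antisaccade"] * 2, "trial_index": [22, 23],
                "removal_reason": ["no_valid_saccade"] * 2,
            }
        )
        assert np.isclose(summarize_task(prim, log).loc[0, "error_rate"], expected)

    def test_observed_error_rates_within_binomial_envelope(self):
        """With coupling off and fixed propensity, per-subject error rates
        stay inside the 99% binomial envelope of the true probability."""
        p_true = 1 / (1 + np.exp(1.0))  # logistic(-1)
        cfg = GeneratorConfig(trials_per_task=240, urgency_coupling=0.0, seed=31)
        from scipy.stats import binom
        lo, hi = binom.ppf([0.005, 0.995], 240, p_true)
        rng = np.random.default_rng(31)
        for i in range(20):
            trials = gen_antisaccade_trials(make_subject(prop=-1.0), cfg, "control", rng)
            assert lo <= trials["is_error"].sum() <= hi


class TestChain:
    def test_chain_is_deterministic_and_conserves_trials(self, small_config):
        events = cohort_events(gen_cohort(small_config, pupil_duration=5.0))
        out1 = process_events(events)
        out2 = process_events(events)
        for a, b in zip(out1, out2):
            pd.testing.assert_frame_equal(a, b)
        prim, log, _ = out1
        n_trials = len(events.groupby(["subject_id", "condition", "task", "trial_index"]))
        assert len(prim) + len(log) == n_trials

    def test_incorrect_antisaccades_faster_than_correct(self):
        cfg = GeneratorConfig(n_patients=8, n_controls=8, urgency_coupling=1.0, seed=17)
        events = cohort_events(gen_cohort(cfg, pupil_duration=5.0))
        prim, _, _ = process_events(events)
        anti = prim[prim["task"] == "antisaccade"]
        err = anti[~anti["correct"].astype(bool)]["latency_ms"].mean()
        corr = anti[anti["correct"].astype(bool)]["latency_ms"].mean()
        assert err < corr
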