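import numpy as np
import pandas as pd
import pytest

from pfsim import ShutdownConfig, simulate_trial
from pfsim.estimands import (
    MonitoringRule,
    derive_exact_times,
    derive_hypothetical,
    derive_interval_dataset,
    derive_treatment_policy,
    determine_cutoff,
    hypothetical_flags,
)
from pfsim.trial import grid_detection_time


def _trial_from(enrolls, true_times, design, shutdown, arms=None):
    """Build a patient table by pushing toy records through the shutdown rules."""
    from pfsim.trial import apply_shutdown

    enrolls = np.asarray(enrolls, dtype=float)
    true_times = np.asarray(true_times, dtype=float)
    detect = grid_detection_time(true_times, design.scan_interval)
    base = pd.DataFrame(
        {
            "arm": np.zeros(len(enrolls), dtype=np.int8)
            if arms is None
            else np.asarray(arms, dtype=np.int8),
            "enrollment": enrolls,
            "true_time": true_times,
            "detection_time": detect,
            "documented_time": detect,
            "documented_calendar": enrolls + detect,
            "via_reopening": np.zeros(len(enrolls), dtype=bool),
        }
    )
    return apply_shutdown(base, design, shutdown)


class TestDetermineCutoff:
    def test_order_statistic_toy(self, small_design):
        trial = pd.DataFrame(
            {
                "documented_calendar": [3.0, 5.0, 9.0, np.inf],
                "via_reopening": [False] * 4,
            }
        )
        cutoff, reached = determine_cutoff(trial, 2, horizon=100.0)
        assert (cutoff, reached) == (5.0, True)
        cutoff, reached = determine_cutoff(trial, 4, horizon=100.0)
        assert (cutoff, reached) == (100.0, False)

    def test_matches_grid_scan_oracle(self, small_design, rng):
        for seed in range(10):
            trial = simulate_trial(small_design, rng=seed)
            cutoff, reached = determine_cutoff(trial, small_design.target_events)
            assert reached
            doc = np.sort(trial["documented_calendar"].to_numpy())
            grid = np.arange(0, 60, 0.01)
            counts = np.searchsorted(doc, grid, side="right")
            oracle = grid[np.argmax(counts >= small_design.target_events)]
            assert abs(cutoff - oracle) <= 0.01

    def test_uncensored_only_excludes_reopening_events(self, design1, shutdown_12_18):
        trial = simulate_trial(design1, shutdown_12_18, rng=7)
        c_all, _ = determine_cutoff(trial, 331, MonitoringRule.ALL_DOCUMENTED_EVENTS)
        c_unc, _ = determine_cutoff(
            trial, 331, MonitoringRule.UNCENSORED_EVENTS_ONLY,
            shutdown=shutdown_12_18,
        )
        assert c_unc >= c_all

    def test_validation(self, small_design):
        trial = pd.DataFrame(
            {"documented_calendar": [1.0], "via_reopening": [False]}
        )
        with pytest.raises(ValueError):
            determine_cutoff(trial, 0)
        with pytest.raises(ValueError):
            determine_cutoff(trial, 2)
        with pytest.raises(ValueError):
            determine_cutoff(trial, 1, horizon=-1.0)


class TestTreatmentPolicy:
    def test_reopening_event_time(self, design1, shutdown_12_18):
        # enrollment 2, detection scan due at calendar 14 (suppressed)
        trial = _trial_from([2.0], [11.3], design1, shutdown_12_18)
        ds = derive_treatment_policy(trial, 30.0, design1, shutdown_12_18)
        assert ds.data.loc[0, "event"] == 1
        assert ds.data.loc[0, "time"] == 16.0  # documented at calendar 18

    def test_all_grid_events_without_shutdown(self, small_design):
        trial = simulate_trial(small_design, rng=3)
        cutoff, _ = determine_cutoff(trial, small_design.target_events)
        ds = derive_treatment_policy(
            trial, cutoff, small_design, ShutdownConfig(),
            target_events=small_design.target_events,
        )
        assert ds.n_events == small_design.target_events
        ev = ds.data[ds.data.event == 1]
        assert np.allclose(ev["time"] % small_design.scan_interval, 0.0)

    def test_censored_at_last_grid_assessment(self, design1):
        trial = _trial_from([1.0], [50.0], design1, ShutdownConfig())
        ds = derive_treatment_policy(trial, 10.5, design1, ShutdownConfig())
        assert ds.data.loc[0, "event"] == 0
        # scans at patient times 2, 4, ... -> last calendar <= 10.5 is 9 (pt 8)
        assert ds.data.loc[0, "time"] == 8.0

    def test_patients_enrolled_after_cutoff_excluded(self, design1):
        trial = _trial_from([1.0, 20.0], [5.0, 5.0], design1, ShutdownConfig())
        ds = derive_treatment_policy(trial, 10.0, design1, ShutdownConfig())
        assert len(ds.data) == 1


class TestHypothetical:
    def test_flagged_event_censored_at_last_prewindow_scan(
        self, design1, shutdown_12_18
    ):
        # enrollment 2: scans at calendar 4..10 survive, 12-16 suppressed;
        # event documented at reopening -> censored at patient time 8
        trial = _trial_from([2.0], [11.3], design1, shutdown_12_18)
        ds = derive_hypothetical(trial, 30.0, design1, shutdown_12_18)
        assert ds.data.loc[0, "event"] == 0
        assert ds.data.loc[0, "time"] == 8.0

    def test_event_documented_before_shutdown_unchanged(
        self, design1, shutdown_12_18
    ):
        trial = _trial_from([2.0], [7.5], design1, shutdown_12_18)
        ds = derive_hypothetical(trial, 30.0, design1, shutdown_12_18)
        assert ds.data.loc[0, "event"] == 1
        assert ds.data.loc[0, "time"] == 8.0

    def test_no_prewindow_assessment_censored_at_zero(self, design1):
        sd = ShutdownConfig(6.0, 6.0)
        # enrolled at 5.5: first scan due at calendar 7.5 (suppressed)
        trial = _trial_from([5.5], [1.0], design1, sd)
        ds = derive_hypothetical(trial, 30.0, design1, sd)
        assert ds.data.loc[0, "event"] == 0
        assert ds.data.loc[0, "time"] == 0.0

    def test_censor_on_true_is_narrower(self, design1, shutdown_12_18):
        trial = simulate_trial(design1, shutdown_12_18, rng=11)
        doc_flags = hypothetical_flags(trial, shutdown_12_18, "documented")
        true_flags = hypothetical_flags(trial, shutdown_12_18, "true")
        assert true_flags.sum() <= doc_flags.sum()

    def test_event_count_never_exceeds_treatment_policy(
        self, design1, shutdown_12_18
    ):
        for seed in range(5):
            trial = simulate_trial(design1, shutdown_12_18, rng=seed)
            cutoff, reached = determine_cutoff(trial, 331)
            tp = derive_treatment_policy(
                trial, cutoff, design1, shutdown_12_18, reached, 331
            )
            hyp = derive_hypothetical(
                trial, cutoff, design1, shutdown_12_18, reached, 331
            )
            assert hyp.n_events <= tp.n_events == 331

    def test_delayed_cutoff_not_earlier_and_restores_count(
        self, design1, shutdown_12_18
    ):
        for seed in range(5):
            trial = simulate_trial(design1, shutdown_12_18, rng=seed)
            c_tp, _ = determine_cutoff(trial, 331)
            c_del, reached = determine_cutoff(
                trial, 331, MonitoringRule.UNCENSORED_EVENTS_ONLY,
                shutdown=shutdown_12_18,
            )
            assert c_del >= c_tp
            ds = derive_hypothetical(
                trial, c_del, design1, shutdown_12_18, reached, 331, delayed=True
            )
            assert ds.n_events == 331


class TestExactTimes:
    def test_event_and_censor_rows(self, design1):
        trial = _trial_from([1.0, 2.0], [5.0, 40.0], design1, ShutdownConfig())
        ds = derive_exact_times(trial, 20.0)
        assert ds.data["event"].tolist() == [1, 0]
        assert ds.data["time"].tolist() == [5.0, 18.0]

    def test_count_equals_target_every_replicate(self, small_design):
        from pfsim.runner import _exact_cutoff

        for seed in range(10):
            trial = simulate_trial(small_design, rng=seed)
            cutoff, _ = _exact_cutoff(trial, small_design.target_events, 240.0)
            ds = derive_exact_times(trial, cutoff)
            assert ds.n_events == small_design.target_events


class TestIntervalDataset:
    def test_plain_grid_interval(self, design1):
        trial = _trial_from([1.0], [5.2], design1, ShutdownConfig())
        ds = derive_interval_dataset(trial, 30.0, design1, ShutdownConfig())
        assert (ds.data.loc[0, "left"], ds.data.loc[0, "right"]) == (4.0, 6.0)

    def test_shutdown_deferred_interval(self, design1, shutdown_12_18):
        # enrollment 2, detection due calendar 14 (suppressed), documented 18;
        # last performed scan before documentation: calendar 10 -> pt 8
        trial = _trial_from([2.0], [11.3], design1, shutdown_12_18)
        ds = derive_interval_dataset(trial, 30.0, design1, shutdown_12_18)
        assert (ds.data.loc[0, "left"], ds.data.loc[0, "right"]) == (8.0, 16.0)

    def test_censored_row_is_half_open(self, design1):
        trial = _trial_from([1.0], [50.0], design1, ShutdownConfig())
        ds = derive_interval_dataset(trial, 16.0, design1, ShutdownConfig())
        assert ds.data.loc[0, "left"] == 14.0
        assert np.isinf(ds.data.loc[0, "right"])

    @pytest.mark.parametrize("start", [6.0, 12.0, 24.0])
    def test_intervals_contain_latent_event_time(self, design1, start):
        sd = ShutdownConfig(start, 6.0)
        for seed in range(4):
            trial = simulate_trial(design1, sd, rng=seed)
            cutoff, reached = determine_cutoff(trial, 331)
            ds = derive_interval_dataset(trial, cutoff, design1, sd, reached)
            sub = trial[trial["enrollment"] <= cutoff]
            truth = sub["true_time"].to_numpy()
            lo = ds.data["left"].to_numpy()
            hi = ds.data["right"].to_numpy()
            assert np.all(lo < truth + 1e-6)
            assert np.all(truth <= hi + 1e-6)
            assert np.all(hi > lo)
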