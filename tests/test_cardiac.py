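"""BPM conversion, Dhr scoring, exclusions and predictor standardization."""

import numpy as np
import pandas as pd
import pytest

from patmodels import (
    DataError,
    apply_exclusions,
    compute_dhr,
    ibi_to_bpm,
    score_trials,
    simulate_cardiac,
    standardize_predictors,
)


def beats_from_bpm(profile, t0=-4.0, t1=8.0):
    """Beat times under a piecewise BPM profile (callable of time)."""
    t, beats = t0, [t0]
    while t < t1:
        t += 60.0 / profile(t)
        beats.append(t)
    return np.asarray(beats)


class TestIbiToBpm:
    @pytest.mark.parametrize("ibi, bpm", [(1.0, 60.0), (0.5, 120.0)])
    def test_constant_rate(self, ibi, bpm):
        times, series = ibi_to_bpm(np.arange(0, 10, ibi))
        assert np.allclose(series, bpm)
        # stamped at the second beat of each interval
        assert np.allclose(times, np.arange(0, 10, ibi)[1:])

    def test_varying_intervals(self):
        times, series = ibi_to_bpm([0.0, 1.0, 1.75])
        assert np.allclose(series, [60.0, 80.0])

    @pytest.mark.parametrize("beats", [[1.0], [0.0, 1.0, 0.5]])
    def test_bad_traces_rejected(self, beats):
        with pytest.raises(DataError):
            ibi_to_bpm(beats)


class TestComputeDhr:
    def test_flat_trace_zero_dhr(self):
        beats = beats_from_bpm(lambda t: 60.0)
        rec = compute_dhr(beats, onset=0.0)
        assert rec["quality"] == "ok"
        assert rec["dhr"] == pytest.approx(0.0, abs=1e-9)
        assert rec["baseline_bpm"] == pytest.approx(60.0, abs=1e-6)

    def test_step_deceleration(self):
        beats = beats_from_bpm(lambda t: 60.0 if t < 0 else 58.0)
        rec = compute_dhr(beats, onset=0.0)
        assert rec["dhr"] == pytest.approx(-2.0, abs=0.1)

    def test_offset_invariance(self):
        """Adding a constant to the whole BPM trace leaves Dhr unchanged."""
        for offset in (0.0, 15.0):
            beats = beats_from_bpm(lambda t: (62.0 + offset) if t < 0 else (59.0 + offset))
            rec = compute_dhr(beats, onset=0.0)
            assert rec["dhr"] == pytest.approx(-3.0, abs=0.1)

    def test_uncovered_window_flagged_not_raised(self):
        beats = beats_from_bpm(lambda t: 60.0, t0=2.0, t1=8.0)  # starts after baseline
        rec = compute_dhr(beats, onset=0.0)
        assert rec["quality"] == "bad" and np.isnan(rec["dhr"])

    def test_implausible_ibi_flagged(self):
        beats = np.array([-4.0, -3.0, -2.0, -1.5, -1.4, -1.3, -1.2, -1.16, 0.0, 2.5, 4.0, 5.0, 6.0, 7.0, 8.0])
        rec = compute_dhr(beats, onset=0.0)
        assert rec["quality"] == "bad"

    def test_noiseless_generator_recovery(self, one_subject_schedule, noiseless_cardiac):
        """simulate -> ibi_to_bpm -> compute_dhr reproduces the latent
        deceleration within ramp-discretization tolerance."""
        traces, table = simulate_cardiac(one_subject_schedule, noiseless_cardiac, seed=3)
        scored = score_trials(table, traces)
        long = scored[scored["is_long"]]
        assert (long["quality"] == "ok").all()
        err = (long["dhr"] - long["dhr_true"]).abs()
        assert float(err.max()) < 0.1


class TestExclusions:
    def _toy(self, **over):
        base = dict(
            subject=[0, 0, 0, 0],
            action_context=["active", "active", "passive", "active"],
            is_long=[True, True, True, False],
            quality=["ok", "ok", "ok", "short"],
            choice=["approach", "approach", "avoid", "approach"],
            rt=[0.150, 0.250, 0.300, 0.400],
        )
        base.update(over)
        return pd.DataFrame(base)

    def test_rt_threshold(self):
        kept, report = apply_exclusions(self._toy())
        assert report["fast_rt"] == 1 and report["short_ami"] == 1
        assert len(kept) == 2

    def test_counts_sum_to_dropped_rows(self):
        table = self._toy()
        kept, report = apply_exclusions(table)
        dropped = report["short_ami"] + report["poor_heart_rate"] + report["fast_rt"]
        assert dropped == len(table) - len(kept) == report["n_input"] - report["n_retained"]

    def test_clean_subject_retains_150(self, one_subject_schedule, noiseless_cardiac):
        traces, table = simulate_cardiac(one_subject_schedule, noiseless_cardiac, seed=3)
        scored = score_trials(table, traces)
        scored["choice"] = "avoid"
        scored["rt"] = 0.5
        kept, report = apply_exclusions(scored)
        assert report["n_retained"] == len(kept) == 150

    def test_all_bad_yields_empty_set(self):
        table = self._toy(quality=["bad"] * 4, is_long=[True] * 4)
        kept, report = apply_exclusions(table)
        assert len(kept) == 0 and report["poor_heart_rate"] == 4


class TestStandardize:
    def _balanced(self):
        money, shocks = np.meshgrid(np.arange(1, 6), np.arange(1, 6))
        frame = pd.DataFrame(
            {
                "subject": 0,
                "money": np.tile(money.ravel(), 2),
                "shocks": np.tile(shocks.ravel(), 2),
                "action_context": ["active"] * 25 + ["passive"] * 25,
            }
        )
        frame["dhr"] = np.linspace(-4, 1, len(frame))
        return frame

    def test_zscores_and_codes(self):
        out, stats = standardize_predictors(self._balanced())
        for col in ("z_money", "z_shocks", "z_dms", "z_dhr"):
            assert abs(out[col].mean()) < 1e-10
            assert out[col].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
        # balanced levels 1..5 give z in {+-1.414, +-0.707, 0}
        expected = np.array([-2, -1, 0, 1, 2]) / np.sqrt(2)
        assert np.allclose(np.sort(out["z_money"].unique()), expected)
        assert set(out["ac_code"]) == {-1.0, 1.0}
        assert (out.loc[out["action_context"] == "active", "ac_code"] == -1).all()

    def test_dms_differenced_on_raw_levels_then_standardized(self):
        out, _ = standardize_predictors(self._balanced())
        raw = out["money"] - out["shocks"]
        assert np.allclose(out["z_dms"], (raw - raw.mean()) / raw.std(ddof=0))

    def test_frozen_stats_reused(self):
        frame = self._balanced()
        _, stats = standardize_predictors(frame)
        shifted = frame.copy()
        shifted["dhr"] += 5.0
        out, _ = standardize_predictors(shifted, stats=stats)
        # same scaling as the frozen stats, so the shift survives
        assert out["z_dhr"].mean() == pytest.approx(5.0 / stats["dhr"][1], abs=1e-9)

    def test_zero_sd_rejected(self):
        frame = self._balanced()
        frame["dhr"] = 1.0
        with pytest.raises(DataError):
            standardize_predictors(frame)
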