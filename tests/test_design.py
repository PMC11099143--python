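"""DV regressors, difference scores, HRF convolution and GLM recovery."""

import numpy as np
import pandas as pd
import pytest

from patmodels import (
    DataError,
    ModelError,
    ParamSet,
    build_design_matrix,
    canonical_hrf,
    dv_diff,
    reference_params,
    regressor_correlations,
    simulate_analysis_table,
    simulate_bold_and_recover,
    split_by_sign,
    trial_dvs_from_params,
)


@pytest.fixture(scope="module")
def dv_table():
    """58 subjects of standardized trials with all DV / DVdiff columns."""
    table = simulate_analysis_table(reference_params("base"), n_subjects=58, seed=203)
    table["dv_base"] = trial_dvs_from_params(table, reference_params("base"))
    for kind in ("av", "vc", "ai"):
        table[f"dv_{kind}"] = trial_dvs_from_params(table, reference_params(kind))
        table[f"dvdiff_{kind}"] = dv_diff(table["dv_base"], table[f"dv_{kind}"])
    return table


@pytest.fixture
def toy_events():
    return pd.DataFrame({"onset": [10.0, 30.0, 50.0, 70.0], "duration": [6.5, 6.2, 6.8, 6.1]})


class TestTrialDvs:
    def test_zero_features_give_intercept(self, feature_frame):
        trials = feature_frame(ac_code=0.0, n=7)
        assert np.allclose(trial_dvs_from_params(trials, reference_params("base")), 0.73)

    def test_kind_mismatch_rejected(self, feature_frame):
        with pytest.raises(ModelError):
            trial_dvs_from_params(feature_frame(), reference_params("av"), kind="vc")

    def test_identical_rows_give_identical_vectors(self, feature_frame):
        trials = feature_frame(z_money=0.5, z_dhr=-1.0, n=4)
        dv = trial_dvs_from_params(trials, reference_params("ai"))
        assert np.ptp(dv) == 0


class TestDvDiff:
    def test_identical_inputs_zero(self):
        assert np.allclose(dv_diff([1.0, -2.0], [1.0, -2.0]), 0.0)

    def test_base_vs_av_hand_trace(self, feature_frame):
        """Trial with z_shocks = +1.414, z_dhr = -1, other features 0.

        Independent term-by-term subtraction of the two parameter rows:
        DV_base = 0.73 - 1.10*1.414 + 0.05*(-1)            = -0.87540
        DV_av   = 0.73 - 1.11*1.414 + 0.04*(-1)
                  + 0.07*1.414*(-1)                         = -0.97852
        DVdiff  = +0.10312.
        """
        z = 2.0 / np.sqrt(2.0)
        trial = feature_frame(z_shocks=z, z_dhr=-1.0, ac_code=0.0)
        diff = dv_diff(
            trial_dvs_from_params(trial, reference_params("base")),
            trial_dvs_from_params(trial, reference_params("av")),
        )
        assert diff[0] == pytest.approx(0.10312, abs=1e-4)

    def test_zero_extra_term_and_shared_params_give_zero_diff(self, feature_frame):
        base = reference_params("base")
        coefs = base.to_dict()
        coefs["shocks:dhr"] = 0.0
        av_like = ParamSet.from_dict("av", coefs)
        rng = np.random.default_rng(0)
        trials = feature_frame(n=30)
        for col in trials.columns:
            trials[col] = rng.normal(size=30)
        diff = dv_diff(
            trial_dvs_from_params(trials, base), trial_dvs_from_params(trials, av_like)
        )
        assert np.allclose(diff, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            dv_diff([1.0, 2.0], [1.0])


class TestSplitBySign:
    def test_partition_rule(self):
        pos, neg = split_by_sign([1.0, -2.0, 0.0])
        assert pos.tolist() == [True, False, False]
        assert neg.tolist() == [False, True, False]

    def test_subsets_cover_nonzero_entries(self):
        rng = np.random.default_rng(5)
        d = np.round(rng.normal(size=200), 1)
        pos, neg = split_by_sign(d)
        assert pos.sum() + neg.sum() == np.count_nonzero(d)
        assert not np.any(pos & neg)


class TestRegressorCorrelations:
    def test_identity_and_negation(self, dv_table):
        same = regressor_correlations(dv_table, "dv_base", "dv_base")
        assert same["mean"] == pytest.approx(1.0) and same["sd"] == pytest.approx(0.0)
        flipped = dv_table.copy()
        flipped["neg"] = -flipped["dv_base"]
        assert regressor_correlations(flipped, "dv_base", "neg")["mean"] == pytest.approx(-1.0)

    def test_full_dvs_nearly_collinear_with_base(self, dv_table):
        """Each freezing-model DV rank-correlates >= 0.998 with the base DV."""
        for kind in ("av", "vc", "ai"):
            r = regressor_correlations(dv_table, "dv_base", f"dv_{kind}")
            assert abs(r["mean"]) >= 0.998

    def test_difference_scores_decorrelate(self, dv_table):
        """Differencing collapses the near-collinearity: mean |rank
        correlation| drops from ~0.998 by roughly an order of magnitude.
        (VC retains the largest residual correlation because its parameter
        row also differs slightly from the base row in the shared terms.)"""
        for kind in ("av", "vc", "ai"):
            r = regressor_correlations(dv_table, "dv_base", f"dvdiff_{kind}")
            assert abs(r["mean"]) < 0.15

    def test_constant_vector_excluded_with_warning(self, dv_table):
        frame = dv_table.copy()
        frame["flat"] = 1.0
        with pytest.warns(UserWarning):
            with pytest.raises(DataError):
                regressor_correlations(frame, "dv_base", "flat")


class TestCanonicalHrf:
    def test_zero_at_origin_peak_and_tail(self):
        t = np.arange(0.0, 32.0, 0.1)
        h = canonical_hrf(t)
        assert h[0] == 0.0
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.2)  # implemented peak
        assert h.max() == pytest.approx(1.0)
        assert abs(h[np.searchsorted(t, 30.0)]) < 0.01

    def test_matches_nilearn_spm_shape(self):
        """Independent oracle: same double-gamma family as the SPM kernel."""
        nl = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        t = np.arange(0.0, 32.0, 0.1)
        mine = canonical_hrf(t)
        ref = nl.spm_hrf(1.0, oversampling=10, time_length=32.0)[: len(t)]
        r = np.corrcoef(mine, ref / ref.max())[0, 1]
        assert r > 0.999


class TestDesignMatrix:
    def test_single_event_column_proportional_to_hrf(self):
        events = pd.DataFrame({"onset": [5.0], "duration": [0.1]})
        dm = build_design_matrix(events, None, run_duration=60.0, highpass=None)
        col = dm.frame["anticipation"].to_numpy()
        t_grid = np.arange(len(col)) * 1.5 - 5.0
        expected = canonical_hrf(np.maximum(t_grid, 0.0))
        mask = (t_grid >= 0.5) & (t_grid <= 25.0)  # inside the kernel support
        ratio = col[mask] / expected[mask]
        assert np.allclose(ratio, ratio[0], rtol=1e-6)

    def test_demeaning_invariance(self, toy_events):
        a = build_design_matrix(toy_events, {"mod": [1.0, 2.0, 3.0, 4.0]}, run_duration=120.0)
        b = build_design_matrix(toy_events, {"mod": [101.0, 102.0, 103.0, 104.0]}, run_duration=120.0)
        assert np.allclose(a.frame["mod"], b.frame["mod"], atol=1e-12)

    def test_linearity_in_modulator_values(self, toy_events):
        m1 = np.array([1.0, -1.0, 2.0, 0.5])
        m2 = np.array([0.3, 0.9, -1.2, 0.1])
        d1 = build_design_matrix(toy_events, {"m": m1}, run_duration=120.0).frame["m"]
        d2 = build_design_matrix(toy_events, {"m": m2}, run_duration=120.0).frame["m"]
        d12 = build_design_matrix(toy_events, {"m": m1 + 2 * m2}, run_duration=120.0).frame["m"]
        assert np.allclose(d12, d1 + 2 * d2, atol=1e-10)

    def test_duplicate_events_rejected(self):
        events = pd.DataFrame({"onset": [10.0, 10.0], "duration": [6.0, 6.0]})
        with pytest.raises(DataError):
            build_design_matrix(events, None, run_duration=60.0)

    def test_all_zero_modulator_dropped_with_warning(self, toy_events):
        with pytest.warns(UserWarning):
            dm = build_design_matrix(toy_events, {"empty": [0.0] * 4}, run_duration=120.0)
        assert "empty" not in dm.columns

    def test_drift_columns_respect_cutoff(self, toy_events):
        dm = build_design_matrix(toy_events, None, run_duration=120.0)
        n_drift = sum(1 for c in dm.columns if c.startswith("drift_"))
        # 120 s of data, 1/128 Hz cutoff -> floor(2 * 120 / 128) = 1 basis function
        assert n_drift == 1


class TestBoldRecovery:
    def test_noiseless_exact_recovery(self, toy_events):
        dm = build_design_matrix(
            toy_events, {"mod": [1.0, -0.5, 2.0, 0.3]}, run_duration=120.0
        )
        rec = simulate_bold_and_recover(dm, {"anticipation": 1.5, "mod": 2.0}, noise_sd=0.0)
        assert np.abs(rec["estimate"] - rec["true"]).max() < 1e-8

    def test_sign_detection_power_on_dvdiff_column(self, dv_table, toy_events):
        """Nonzero effect on a DVdiff-style modulator is detected with the
        right sign in nearly every noise realization."""
        sub = dv_table[dv_table["subject"] == 0].head(4)
        dm = build_design_matrix(
            toy_events, {"dvdiff_av": sub["dvdiff_av"].to_numpy()}, run_duration=120.0
        )
        hits = 0
        for seed in range(100):
            rec = simulate_bold_and_recover(dm, {"dvdiff_av": 2.0}, noise_sd=0.3, seed=seed)
            hits += rec.loc["dvdiff_av", "estimate"] > 0
        assert hits >= 95

    def test_duplicate_column_named_in_rank_error(self, toy_events):
        dm = build_design_matrix(toy_events, {"m": [1.0, 2.0, 3.0, 4.0]}, run_duration=120.0)
        dm.frame["m_copy"] = dm.frame["m"]
        dm.roles["m_copy"] = "parametric"
        with pytest.raises(ModelError, match="m"):
            simulate_bold_and_recover(dm, {"m": 1.0}, noise_sd=0.1)

    def test_sign_split_spans_unsplit_column(self, toy_events):
        """positive + negative sub-regressors + event indicator reproduce the
        unsplit DVdiff column (superposition at microtime level)."""
        vals = np.array([0.8, -1.2, 0.4, -0.3])
        pos, neg = split_by_sign(vals)
        dm_all = build_design_matrix(toy_events, {"d": vals}, run_duration=120.0, highpass=None)
        dm_parts = build_design_matrix(
            toy_events,
            {"d_pos": np.where(pos, vals, 0.0), "d_neg": np.where(neg, vals, 0.0)},
            run_duration=120.0,
            highpass=None,
        )
        lhs = dm_all.frame["d"].to_numpy()
        X = np.column_stack(
            [
                dm_parts.frame["d_pos"],
                dm_parts.frame["d_neg"],
                dm_parts.frame["anticipation"],
            ]
        )
        coef, res, *_ = np.linalg.lstsq(X, lhs, rcond=None)
        fitted = X @ coef
        assert np.allclose(fitted, lhs, atol=1e-8)
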