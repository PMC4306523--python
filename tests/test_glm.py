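"""First-level GLM: events handling, HRF, design matrix, OLS, contrasts."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from rivaldcm.cohort import CohortConfig, simulate_cohort
from rivaldcm.glm import (
    FirstLevelGLM,
    HRFSpec,
    build_design_matrix,
    canonical_hrf,
    contrast_rivalry_gt_replay,
    correct_event_times,
    derive_switch_events,
    estimate_mean_rt,
    fit_glm,
    group_contrast_ttest,
    mean_dominance_from_events,
    read_events_tsv,
    trim_initial_volumes,
    write_events_tsv,
)


def ev(rows):
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type",
                                       "response_time"])


class TestEventCorrection:
    def test_zero_mean_rt_is_identity(self):
        events = ev([(5.0, 0.0, "rivalry_switch", np.nan)])
        out = correct_event_times(events, 0.0)
        pd.testing.assert_frame_equal(out, events)

    def test_switch_onset_shifted_earlier_by_mean_rt(self):
        events = ev([(0.0, 31.5, "stimulation_rivalry", np.nan),
                     (5.0, 0.0, "rivalry_switch", np.nan)])
        out = correct_event_times(events, 0.90)
        sw = out[out["trial_type"] == "rivalry_switch"]
        assert sw["onset"].iloc[0] == pytest.approx(4.10)
        stim = out[out["trial_type"] == "stimulation_rivalry"]
        assert stim["onset"].iloc[0] == 0.0  # non-switch rows untouched

    def test_onsets_clip_at_zero(self):
        events = ev([(0.5, 0.0, "replay_switch", np.nan)])
        out = correct_event_times(events, 0.90)
        assert out["onset"].iloc[0] == 0.0

    def test_negative_mean_rt_rejected(self):
        with pytest.raises(ValueError):
            correct_event_times(ev([]), -0.1)


class TestSwitchDerivation:
    def test_switches_are_label_changes_excluding_first_and_mixed(self):
        events = ev([
            (0.0, 20.0, "stimulation_rivalry", np.nan),
            (1.0, 0.0, "press_toward", np.nan),     # first press: no switch
            (5.0, 0.0, "press_mixed", np.nan),      # mixed: never a switch
            (5.3, 0.0, "press_away", np.nan),       # switch 1
            (9.0, 0.0, "press_away", np.nan),       # same label: no switch
            (12.0, 0.0, "press_toward", np.nan),    # switch 2
        ])
        sw = derive_switch_events(events)
        assert list(sw["trial_type"]) == ["rivalry_switch"] * 2
        assert list(sw["onset"]) == [5.3, 12.0]

    def test_mean_rt_estimated_from_replay_response_times(self):
        events = ev([
            (0.0, 20.0, "stimulation_replay", np.nan),
            (3.0, 0.0, "press_toward", 0.8),
            (8.0, 0.0, "press_away", 1.0),
        ])
        assert estimate_mean_rt(events) == pytest.approx(0.9)
        with pytest.raises(ValueError):
            estimate_mean_rt(ev([(0.0, 20.0, "stimulation_rivalry", np.nan)]))

    def test_events_tsv_roundtrip_preserves_na(self, tmp_path):
        events = ev([(0.0, 10.5, "fixation", np.nan),
                     (11.2, 0.0, "press_toward", 0.82)])
        write_events_tsv(events, tmp_path / "ev.tsv")
        with open(tmp_path / "ev.tsv") as fh:
            assert "n/a" in fh.read()
        back = read_events_tsv(tmp_path / "ev.tsv")
        assert np.isnan(back["response_time"].iloc[0])
        assert back["response_time"].iloc[1] == pytest.approx(0.82)


class TestHRF:
    def test_shape_positive_peak_then_undershoot(self):
        h = canonical_hrf(HRFSpec(), dt=0.1)
        peak = np.argmax(h)
        assert h[peak] > 0
        assert h.min() < 0
        assert np.argmin(h) > peak

    def test_peak_at_gamma_mode(self):
        dt = 0.05
        h = canonical_hrf(HRFSpec(), dt=dt)
        # mode of gamma(shape=6, scale=1) is (6-1)*1 = 5 s
        assert abs(np.argmax(h) * dt - 5.0) <= dt

    def test_discrete_integral_stable_under_refinement(self):
        s1 = canonical_hrf(HRFSpec(), 0.1).sum() * 0.1
        s2 = canonical_hrf(HRFSpec(), 0.05).sum() * 0.05
        assert abs(s1 - s2) / abs(s2) < 0.01

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            HRFSpec(dispersion=0.0)
        with pytest.raises(ValueError):
            canonical_hrf(HRFSpec(), dt=0.0)


class TestDesignMatrix:
    def test_no_events_gives_zero_task_columns(self):
        X = build_design_matrix(ev([]), n_vols=20)
        for col in ("fixation", "stimulation", "rivalry_switch",
                    "replay_switch"):
            assert np.all(X[col] == 0)
        assert np.all(X["intercept"] == 1)

    def test_single_impulse_at_origin_equals_sampled_kernel(self):
        spec = HRFSpec()
        X = build_design_matrix(ev([(0.0, 0.0, "rivalry_switch", np.nan)]),
                                hrf=spec, n_vols=12, TR=2.1)
        kernel = canonical_hrf(spec, 2.1 / spec.microtime_bins)
        expect = kernel[np.arange(12) * spec.microtime_bins]
        assert np.allclose(X["rivalry_switch"], expect, atol=1e-12)

    def test_boxcar_equals_superposition_of_shifted_impulses(self):
        spec = HRFSpec()
        dt = 2.1 / spec.microtime_bins
        onset, dur, n_vols = 4.2, 6.3, 24
        X = build_design_matrix(
            ev([(onset, dur, "stimulation_rivalry", np.nan)]),
            hrf=spec, n_vols=n_vols, TR=2.1)
        # oracle: sum shifted kernels over every microtime bin in the support
        kernel = canonical_hrf(spec, dt)
        T = n_vols * spec.microtime_bins + 1
        acc = np.zeros(T)
        a, b = int(round(onset / dt)), int(round((onset + dur) / dt))
        for k in range(a, b):
            seg = kernel[: T - k]
            acc[k:k + len(seg)] += seg
        expect = acc[np.arange(n_vols) * spec.microtime_bins]
        assert np.allclose(X["stimulation"], expect, atol=1e-10)

    def test_event_beyond_run_end_is_reported(self):
        with pytest.raises(ValueError, match="rivalry_switch@99"):
            build_design_matrix(ev([(99.0, 0.0, "rivalry_switch", np.nan)]),
                                n_vols=10, TR=2.1)

    def test_nuisance_columns_are_appended(self):
        nuis = pd.DataFrame({"motion_x": np.arange(10.0)})
        X = build_design_matrix(ev([]), n_vols=10, nuisance=nuis)
        assert "nuisance_motion_x" in X.columns


class TestOLS:
    def _design(self, n_vols=80, seed=0):
        rng = np.random.default_rng(seed)
        events = ev([(2.0, 20.0, "stimulation_rivalry", np.nan),
                     (50.0, 20.0, "stimulation_replay", np.nan),
                     (6.0, 0.0, "rivalry_switch", np.nan),
                     (55.0, 0.0, "replay_switch", np.nan),
                     (0.0, 2.0, "fixation", np.nan)])
        return build_design_matrix(events, n_vols=n_vols, TR=2.1), rng

    def test_noiseless_coefficients_recovered_to_machine_precision(self):
        X, _ = self._design()
        beta = np.array([[0.5], [1.2], [2.0], [-0.7], [0.3]])
        Y = X.to_numpy() @ beta
        fit = fit_glm(Y, X)
        assert np.allclose(fit.coef, beta, atol=1e-10)

    def test_joint_row_permutation_leaves_estimates_unchanged(self):
        X, rng = self._design()
        Y = rng.normal(size=(len(X), 2))
        perm = rng.permutation(len(X))
        f1 = fit_glm(Y, X)
        f2 = fit_glm(Y[perm], X.iloc[perm].reset_index(drop=True))
        assert np.allclose(f1.coef, f2.coef, atol=1e-10)

    def test_rank_deficiency_names_collinear_columns(self):
        X, rng = self._design()
        X["dup"] = X["stimulation"]
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(rng.normal(size=(len(X), 1)), X)

    def test_contrast_semantics(self):
        X, _ = self._design()
        cols = list(X.columns)
        beta = np.zeros((len(cols), 1))
        beta[cols.index("rivalry_switch")] = 1.0
        beta[cols.index("replay_switch")] = 0.5
        fit = fit_glm(X.to_numpy() @ beta, X)
        est, _ = contrast_rivalry_gt_replay(fit)
        assert est[0] == pytest.approx(0.5, abs=1e-10)
        # equal true responses -> zero contrast
        beta[cols.index("rivalry_switch")] = 0.5
        fit2 = fit_glm(X.to_numpy() @ beta, X)
        est2, _ = contrast_rivalry_gt_replay(fit2)
        assert est2[0] == pytest.approx(0.0, abs=1e-10)

    def test_missing_switch_column_rejected(self):
        X = build_design_matrix(ev([(0.0, 4.2, "fixation", np.nan)]),
                                n_vols=10)[["fixation", "intercept"]]
        fit = FirstLevelGLM().fit(X, np.zeros((10, 1))).to_fit()
        with pytest.raises(ValueError, match="rivalry_switch"):
            contrast_rivalry_gt_replay(fit)

    def test_t_statistics_null_distribution(self):
        """On pure noise the contrast t follows Student t with the OLS df:
        calibrated type-I error and a KS check of the full t sample."""
        X, rng = self._design(n_vols=60, seed=42)
        n_sim = 1000
        Y = rng.normal(size=(60, n_sim))
        fit = fit_glm(Y, X)
        _, tstats = contrast_rivalry_gt_replay(fit)
        df = fit.df_resid
        crit = scipy.stats.t.ppf(0.975, df)
        rate = np.mean(np.abs(tstats) > crit)
        assert abs(rate - 0.05) <= 0.015
        ks = scipy.stats.kstest(tstats, scipy.stats.t(df).cdf)
        assert ks.pvalue > 0.01

    def test_estimator_interface(self):
        X, rng = self._design()
        est = FirstLevelGLM().fit(X, rng.normal(size=(len(X), 3)))
        assert est.coef_.shape == (len(X.columns), 3)
        assert est.df_resid_ == len(X) - len(X.columns)
        assert est.get_params() == {"check_rank": True}
        # residuals orthogonal to the design (normal equations)
        assert np.allclose(X.to_numpy().T @ est.residuals_, 0.0, atol=1e-8)


class TestEndToEnd:
    def test_trim_initial_volumes_shifts_clock_and_clips(self):
        from rivaldcm.forward import BOLDSeries
        bold = BOLDSeries(y=np.arange(20.0).reshape(-1, 1), TR=2.1)
        events = ev([(0.0, 10.5, "fixation", np.nan),
                     (10.5, 31.5, "stimulation_rivalry", np.nan),
                     (2.0, 0.0, "press_toward", np.nan)])
        bt, et = trim_initial_volumes(bold, events, 5)
        assert bt.n_volumes == 15
        assert bt.y[0, 0] == 5.0
        assert "press_toward" not in set(et["trial_type"])  # before new origin
        stim = et[et["trial_type"] == "stimulation_rivalry"]
        assert stim["onset"].iloc[0] == pytest.approx(0.0)

    def test_stronger_rivalry_drive_at_pspl_yields_positive_group_contrast(
            self, model_space):
        """Simulated subjects whose rivalry switches drive pSPL harder than
        replay switches show a positive group-mean contrast at pSPL."""
        from rivaldcm.cohort import SubjectGroundTruth, BehavioralProfile
        from rivaldcm.cohort import simulate_subject
        from rivaldcm.forward import parameters_from_masks
        from rivaldcm.model_space import MODULABLE_CONNECTIONS

        model = model_space[31]  # pSPL receives switch input
        cfg = CohortConfig(n_subjects=5, n_runs=1, trials_per_run=4,
                           rivalry_per_run=2, dt=0.3, model=model,
                           noise_sd=0.2)
        contrasts = []
        for i in range(4):
            params = parameters_from_masks(
                model,
                a_values={("r-V5", "r-pSPL"): 0.2, ("r-pSPL", "r-V5"): 0.1,
                          ("r-pSPL", "r-aSPL"): 0.2, ("r-aSPL", "r-pSPL"): 0.1},
                c_values={("stimulation", "r-V5"): 0.04,
                          ("rivalry_switch", "r-V5"): 0.15,
                          ("replay_switch", "r-V5"): 0.15,
                          ("rivalry_switch", "r-pSPL"): 0.30,
                          ("replay_switch", "r-pSPL"): 0.05})
            truth = SubjectGroundTruth(f"sub-{i}", params,
                                       BehavioralProfile(),
                                       {c: 0.0 for c in MODULABLE_CONNECTIONS},
                                       4.5)
            subj = simulate_subject(truth, cfg, seed=100 + i)
            run = subj.runs[0]
            bt, et = trim_initial_volumes(run.bold, run.events, 5)
            mrt = estimate_mean_rt(et)
            full = pd.concat(
                [et, correct_event_times(derive_switch_events(et), mrt)],
                ignore_index=True).sort_values("onset", kind="stable")
            X = build_design_matrix(full, n_vols=bt.n_volumes, TR=2.1)
            est, _ = contrast_rivalry_gt_replay(fit_glm(bt, X))
            contrasts.append(est)
        group = group_contrast_ttest(np.array(contrasts))
        assert group.loc[1, "mean_contrast"] > 0  # pSPL row

    def test_observed_dominance_matches_generating_profile(self):
        cfg = CohortConfig(n_subjects=5, n_runs=2, trials_per_run=6,
                           rivalry_per_run=3, dt=0.3,
                           gamma_c=(0, 0, 0, 0), linking_noise_sd=0.0)
        cohort = simulate_cohort(cfg)
        events = pd.concat([r.events for s in cohort.subjects for r in s.runs],
                           ignore_index=True)
        # censored-epoch exclusion leaves a slight downward bias vs 4.5 s
        obs = np.mean([mean_dominance_from_events(r.events)
                       for s in cohort.subjects for r in s.runs])
        assert 3.8 <= obs <= 5.0
        mrt = estimate_mean_rt(events)
        assert 0.7 <= mrt <= 1.1
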