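"""Design construction, OLS fitting, max-statistic permutation inference,
and the GLM-spectrum."""

import numpy as np
import pytest
from scipy import signal, stats

from ephys_batch.glm import (
    GLM,
    DesignMatrix,
    build_first_level_design,
    build_group_design,
    fit_glm,
    glm_spectrum,
    max_stat_permutation,
)


class TestDesigns:
    def test_three_conditions_give_three_regressors_two_contrasts(self):
        names = ["famous", "unfamiliar", "scrambled"] * 10
        d = build_first_level_design(
            names, ["famous", "unfamiliar", "scrambled"]
        )
        assert d.n_regressors == 3
        assert len(d.contrasts) == 2
        assert d.contrasts[0][0] == "mean"
        assert np.allclose(d.contrasts[0][1], 1 / 3)
        assert list(d.contrasts[1][1]) == [0.5, 0.5, -1.0]

    def test_single_condition_is_a_column_of_ones(self):
        d = build_first_level_design(["a"] * 5, ["a"])
        assert np.array_equal(d.X, np.ones((5, 1)))

    def test_rows_are_one_hot(self, rng):
        conds = ["a", "b", "c"]
        names = [conds[i] for i in rng.integers(0, 3, 30)]
        d = build_first_level_design(names, conds)
        assert np.array_equal(d.X.sum(axis=1), np.ones(30))
        assert set(np.unique(d.X)) == {0.0, 1.0}

    def test_unknown_label_listed_in_error(self):
        with pytest.raises(ValueError, match="mystery"):
            build_first_level_design(["a", "mystery"], ["a"])

    def test_group_design_19_subjects(self):
        ids = [f"sub{s:03d}" for s in range(19) for _ in range(6)]
        d = build_group_design(ids)
        assert d.n_regressors == 19
        assert len(d.contrasts) == 1
        assert np.allclose(d.contrasts[0][1], 1 / 19)

    def test_group_design_column_sums_count_sessions(self):
        ids = ["s1", "s1", "s1", "s2", "s3", "s3"]
        d = build_group_design(ids)
        assert list(d.X.sum(axis=0)) == [3.0, 1.0, 2.0]

    def test_single_subject_single_column(self):
        d = build_group_design(["s1", "s1"])
        assert d.X.shape == (2, 1)


class TestFit:
    def test_intercept_model_reproduces_one_sample_t(self, rng):
        Y = rng.standard_normal((15, 4)) + 0.3
        d = DesignMatrix(np.ones((15, 1)), ["mean"], [("mean", [1.0])])
        res = fit_glm(Y, d)
        t_ref = stats.ttest_1samp(Y, 0.0).statistic
        assert np.allclose(res.tstat[0], t_ref)
        assert res.dof == 14

    def test_coefficients_recovered_on_simulated_data(self, rng):
        n, p = 200, 3
        X = rng.standard_normal((n, p))
        beta_true = np.array([1.0, -0.5, 0.25])
        sigma = 0.1
        Y = X @ beta_true + sigma * rng.standard_normal(n)
        d = DesignMatrix(X, list("abc"), [("a", [1, 0, 0])])
        res = fit_glm(Y, d)
        assert np.abs(res.beta[:, 0] - beta_true).max() < 5 * sigma / np.sqrt(n)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 2))
        d = DesignMatrix(X, list("abc"), [("c1", [1.0, -1.0, 0.0])])
        res = fit_glm(Y, d)
        beta_ref = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(res.beta, beta_ref)
        c = np.array([1.0, -1.0, 0.0])
        resid = Y - X @ beta_ref
        s2 = (resid**2).sum(axis=0) / 7
        var_ref = s2 * (c @ np.linalg.inv(X.T @ X) @ c)
        assert np.allclose(res.varcope[0], var_ref)

    def test_two_sample_design_matches_ttest(self, rng):
        y1, y2 = rng.standard_normal(12), rng.standard_normal(10) + 0.5
        Y = np.concatenate([y1, y2])[:, None]
        X = np.zeros((22, 2))
        X[:12, 0] = 1
        X[12:, 1] = 1
        d = DesignMatrix(X, ["g1", "g2"], [("diff", [1.0, -1.0])])
        res = fit_glm(Y, d)
        t_ref = stats.ttest_ind(y1, y2).statistic
        assert res.tstat[0, 0] == pytest.approx(t_ref)

    def test_underdetermined_rejected(self, rng):
        X = rng.standard_normal((3, 3))
        with pytest.raises(ValueError):
            fit_glm(rng.standard_normal((3, 1)), DesignMatrix(X, list("abc")))

    def test_summary_mentions_contrasts(self, rng):
        Y = rng.standard_normal((15, 4))
        d = DesignMatrix(np.ones((15, 1)), ["mean"], [("mean", [1.0])])
        text = GLM(Y, d).fit().summary()
        assert "mean" in text and "dof: 14" in text


class TestPermutation:
    def _mean_design(self, n):
        return DesignMatrix(np.ones((n, 1)), ["mean"], [("mean", [1.0])])

    def test_min_p_bounded_by_one_over_nperms(self, rng):
        """The identity permutation is always included, so even an
        overwhelming effect cannot reach p below 1/n_perms (random draws may
        duplicate the identity orbit, so a small multiple is allowed)."""
        Y = rng.standard_normal((10, 5)) + 10.0
        res = max_stat_permutation(Y, self._mean_design(10), n_perms=100, seed=0)
        assert 1 / 100 <= res.pvalue <= 5 / 100

    def test_fast_and_general_paths_agree(self, rng):
        Y = rng.standard_normal((12, 8))
        d = self._mean_design(12)
        fast = max_stat_permutation(Y, d, n_perms=150, seed=4)
        general = max_stat_permutation(
            Y, d, n_perms=150, seed=4, groups=list(range(12))
        )
        assert fast.threshold == pytest.approx(general.threshold)
        assert np.array_equal(fast.sig_mask, general.sig_mask)

    def test_null_familywise_error_calibrated(self):
        """Zero-effect simulations: FWER at alpha=0.05 inside the binomial
        band [0.02, 0.09] over 200 repetitions of 500 permutations."""
        d = self._mean_design(12)
        rej = 0
        n_sims = 200
        for sim in range(n_sims):
            r = np.random.default_rng(50_000 + sim)
            Y = r.standard_normal((12, 40))
            res = max_stat_permutation(Y, d, n_perms=500, seed=sim)
            rej += res.pvalue <= 0.05
        assert 0.02 <= rej / n_sims <= 0.09

    def test_planted_effect_found_only_inside_window(self):
        hits, false_out = 0, 0
        n_runs = 10
        for run in range(n_runs):
            r = np.random.default_rng(run)
            Y = r.standard_normal((14, 60))
            Y[:, 20:30] += 1.5  # strong effect confined to a known window
            res = max_stat_permutation(
                Y, self._mean_design(14), n_perms=300, seed=run
            )
            inside = res.sig_mask[20:30]
            outside = np.concatenate([res.sig_mask[:20], res.sig_mask[30:]])
            hits += inside.any()
            false_out += outside.any()
        assert hits >= int(0.9 * n_runs)
        assert false_out <= n_runs - int(0.9 * n_runs)

    def test_scope_mask_restricts_null_and_significance(self, rng):
        Y = rng.standard_normal((12, 30))
        Y[:, 25] += 5.0
        mask = np.zeros(30, dtype=bool)
        mask[:20] = True  # effect dimension excluded from scope
        res = max_stat_permutation(
            Y, self._mean_design(12), n_perms=200, seed=1, scope_mask=mask
        )
        assert not res.sig_mask[25]

    def test_label_permutation_scheme(self, rng):
        names = ["a", "b"] * 10
        d = build_first_level_design(
            names, ["a", "b"], {"diff": [1.0, -1.0]}
        )
        Y = rng.standard_normal((20, 6))
        Y[np.array(names) == "a", :2] += 2.0
        res = max_stat_permutation(
            Y, d, n_perms=200, seed=0, scheme="labels"
        )
        assert res.sig_mask[:2].all()

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            max_stat_permutation(
                rng.standard_normal((10, 3)), self._mean_design(10), n_perms=10
            )


class TestFullPipelineRecovery:
    def test_group_test_flags_planted_parcels_and_window(self):
        """Multi-subject epochs with a planted faces-vs-scrambled effect:
        first-level GLMs per session, subject-indicator group design on the
        copes, and the max-stat sign-flip test flags (only) the planted
        parcels inside the planted time window."""
        from ephys_batch.synthetic import SimulationSpec, simulate_evoked_effect

        copes, subj_ids = [], []
        n_parcels = 6
        for sub in range(8):
            for ses in range(2):
                ep, mask = simulate_evoked_effect(
                    SimulationSpec(n_parcels=n_parcels, n_events=48,
                                   effect_size=0.8, seed=10 + sub),
                    subject=sub, session=ses,
                )
                d = build_first_level_design(
                    ep.trial_names, ["famous", "unfamiliar", "scrambled"]
                )
                res = fit_glm(ep.data.reshape(ep.n_trials, -1), d)
                copes.append(res.cope[1])  # faces vs scrambled
                subj_ids.append(f"sub{sub}")
        group = build_group_design(subj_ids)
        perm = max_stat_permutation(
            np.array(copes), group, n_perms=500, seed=1,
            scheme="sign_flip", groups=subj_ids,
        )
        sig = perm.sig_mask.reshape(n_parcels, -1)
        flagged_parcels = set(np.nonzero(sig)[0].tolist())
        assert flagged_parcels
        assert flagged_parcels <= {0, 1}  # the planted parcels
        times = ep.times
        sig_times = times[np.nonzero(sig)[1]]
        assert sig_times.min() >= 0.05 and sig_times.max() < 0.3


class TestGLMSpectrum:
    def test_intercept_equals_welch_average_exactly(self, rng):
        x = rng.standard_normal((3, 5000))
        fs = 250.0
        res = glm_spectrum(x, window_s=2.0, overlap=0.5, sfreq=fs)
        f_ref, p_ref = signal.welch(
            x, fs, nperseg=500, noverlap=250, window="hann", detrend="constant"
        )
        assert np.allclose(res.freqs, f_ref)
        assert np.allclose(res.beta[0].T, p_ref, rtol=1e-10)

    def test_pure_sine_peaks_at_its_bin(self):
        fs = 250.0
        t = np.arange(5000) / fs
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        res = glm_spectrum(x, window_s=2.0, overlap=0.5, sfreq=fs)
        assert res.freqs[np.argmax(res.beta[0][:, 0])] == pytest.approx(10.0)

    def test_amplitude_ramp_covariate_finds_trend(self, rng):
        fs = 250.0
        t = np.arange(5000) / fs
        amp = np.linspace(0.5, 2.0, 5000)
        x = (amp * np.sin(2 * np.pi * 10 * t)
             + 0.05 * rng.standard_normal(5000))[None, :]
        n_windows = (5000 - 250) // 250
        res = glm_spectrum(
            x, window_s=2.0, overlap=0.5, sfreq=fs,
            covariates={"window_index": np.arange(n_windows, dtype=float)},
        )
        trend = res.beta[1][:, 0]
        peak = np.argmax(trend)
        assert res.freqs[peak] == pytest.approx(10.0)
        off = np.delete(np.abs(trend), peak)
        assert off.max() < 0.5 * trend[peak]

    def test_fewer_windows_than_regressors_rejected(self, rng):
        x = rng.standard_normal((1, 300))
        cov = {f"c{i}": np.arange(1, dtype=float) for i in range(3)}
        with pytest.raises(ValueError):
            glm_spectrum(x, window_s=1.2, overlap=0.0, sfreq=250.0,
                         covariates={"a": np.zeros(1)})

    def test_window_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            glm_spectrum(rng.standard_normal((1, 100)), window_s=0.01,
                         sfreq=250.0)
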