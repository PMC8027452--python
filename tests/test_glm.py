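"""Design construction, AR(1) GLM, contrasts, group inference."""

import numpy as np
import pytest
from scipy import stats as sps

import coeruleus as co
from coeruleus.glm import (BlockSchedule, Hrf, build_design, cluster_fwe,
                           contrast, contrast_weights, fit_glm_ar1,
                           group_onesample, roi_mean)


class TestSchedule:
    def test_alternating_layout(self):
        s = BlockSchedule.alternating()
        assert len(s.onsets["drug"]) == 6
        assert len(s.onsets["neutral"]) == 6
        assert s.onsets["drug"][0] == 2.0       # fixation first
        assert s.onsets["neutral"][0] == 47.0
        assert s.end_time() == pytest.approx(11 * 45 + 2 + 36)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BlockSchedule(conditions=("a", "b"),
                          onsets={"a": np.array([0.0]),
                                  "b": np.array([5.0])},
                          durations={"a": np.array([10.0]),
                                     "b": np.array([5.0])})


class TestBuildDesign:
    def test_empty_schedule_gives_nuisance_plus_intercept(self, rng):
        s = BlockSchedule(conditions=())
        nuis = rng.normal(size=(50, 2))
        d = build_design(s, 1.0, 50, nuisance=nuis, high_pass=None)
        assert d.matrix.shape == (50, 3)
        assert d.names == ["nuisance00", "nuisance01", "intercept"]

    def test_event_regressor_peaks_5_to_7s(self):
        """A brief event's convolved regressor peaks where the canonical
        HRF does, 5-7 s after onset."""
        s = BlockSchedule(conditions=("a",),
                          onsets={"a": np.array([10.0])},
                          durations={"a": np.array([1.0])})
        d = build_design(s, 1.0, 60, high_pass=None)
        assert 5 <= np.argmax(d.matrix[:, 0]) - 10 <= 7

    def test_block_regressor_peaks_after_sustained_response(self):
        """A 6 s block integrates the HRF: its regressor peaks later than
        a brief event's, 7-11 s after onset."""
        s = BlockSchedule(conditions=("a",),
                          onsets={"a": np.array([10.0])},
                          durations={"a": np.array([6.0])})
        d = build_design(s, 1.0, 60, high_pass=None)
        assert 7 <= np.argmax(d.matrix[:, 0]) - 10 <= 11

    def test_identical_conditions_flag_rank_deficiency(self):
        on = np.array([5.0, 60.0])
        du = np.array([10.0, 10.0])
        s = BlockSchedule(conditions=("a",), onsets={"a": on},
                          durations={"a": du})
        d1 = build_design(s, 1.0, 120, high_pass=None)
        # duplicate the condition column manually
        import numpy as _np
        from coeruleus.glm import Design
        dup = Design(matrix=_np.column_stack([d1.matrix[:, 0],
                                              d1.matrix[:, 0],
                                              d1.matrix[:, -1]]),
                     names=["a", "a_copy", "intercept"])
        assert dup.rank_deficient
        assert "a" in dup.collinear_columns() \
            or "a_copy" in dup.collinear_columns()

    def test_schedule_must_fit_window(self):
        s = BlockSchedule.alternating()
        with pytest.raises(ValueError, match="fit"):
            build_design(s, 1.0, 100)


class TestFitGlmAr1:
    def test_noiseless_recovery_exact(self, rng):
        X = np.column_stack([rng.normal(size=(80, 3)), np.ones(80)])
        beta = rng.normal(size=4)
        fit = fit_glm_ar1(X @ beta, X)
        assert np.max(np.abs(fit.beta[:, 0] - beta)) <= 1e-8

    def test_rho_recovery_large_t(self):
        """AR(1) noise with rho = 0.4 at T = 5000: estimate in
        [0.35, 0.45]."""
        rng = np.random.default_rng(7)
        T = 5000
        e = np.empty(T)
        e[0] = rng.normal()
        for t in range(1, T):
            e[t] = 0.4 * e[t - 1] + rng.normal()
        X = np.column_stack([rng.normal(size=T), np.ones(T)])
        fit = fit_glm_ar1(X @ np.array([1.0, 2.0]) + e, X)
        assert 0.35 <= fit.rho <= 0.45

    def test_white_noise_matches_ols_oracle(self, rng):
        """With white noise the AR(1) fit reduces to plain OLS."""
        T = 4000
        X = np.column_stack([rng.normal(size=(T, 2)), np.ones(T)])
        y = X @ np.array([0.5, -1.0, 3.0]) + rng.normal(size=T)
        fit = fit_glm_ar1(y, X)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(fit.beta[:, 0] - ols)
                      / np.maximum(np.abs(ols), 1)) < 1e-3
        assert abs(fit.rho) < 0.1

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.normal(size=60)
        X = np.column_stack([x, 2 * x, np.ones(60)])
        from coeruleus.glm import Design
        d = Design(matrix=X, names=["a", "b", "intercept"])
        with pytest.raises(ValueError, match="collinear"):
            fit_glm_ar1(rng.normal(size=60), d)

    def test_df_accounting(self, rng):
        T = 100
        X = np.column_stack([rng.normal(size=(T, 3)), np.ones(T)])
        fit = fit_glm_ar1(rng.normal(size=(T, 2)), X)
        assert fit.df == T - 4
        assert -1 < fit.rho < 1


class TestContrast:
    def _fit(self, rng, V=5):
        T = 120
        X = np.column_stack([rng.normal(size=(T, 2)), np.ones(T)])
        Y = rng.normal(size=(T, V))
        return fit_glm_ar1(Y, X)

    def test_zero_weights_zero_map(self, rng):
        fit = self._fit(rng)
        assert np.array_equal(contrast(fit, np.zeros(3)), np.zeros(5))

    def test_antisymmetry(self, rng):
        fit = self._fit(rng)
        w = np.array([1.0, -1.0, 0.0])
        assert np.allclose(contrast(fit, w), -contrast(fit, -w))

    def test_linearity_in_weights(self, rng):
        fit = self._fit(rng)
        w1 = np.array([1.0, 0.0, 0.0])
        w2 = np.array([0.0, 1.0, 0.0])
        assert np.allclose(contrast(fit, 2 * w1 + 3 * w2),
                           2 * contrast(fit, w1) + 3 * contrast(fit, w2))

    def test_length_mismatch_error(self, rng):
        fit = self._fit(rng)
        with pytest.raises(ValueError, match="length"):
            contrast(fit, np.zeros(5))

    def test_drug_activation_detected(self):
        """Simulated drug-only activation gives a positive drug-neutral
        contrast at activated voxels in >= 95% of seeded runs."""
        import dataclasses
        base = co.BoldSimParams(gamma_drug=0.0, gamma_neutral=0.0,
                                drug_activation=0.5, noise_sd=0.5,
                                physio_amp=0.0, motion_amp=0.0,
                                target_shape=(1, 1, 1))
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            run, _ = co.make_bold_run(dataclasses.replace(base, seed=s))
            d = build_design(run.schedule, run.tr, len(run.seed_series),
                             high_pass=None)
            fit = fit_glm_ar1(run.targets, d)
            w = contrast_weights(d, "drug", "neutral")
            hits += contrast(fit, w)[0] > 0
        assert hits >= 0.95 * n_rep


class TestRoiMean:
    def test_constant_map(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert roi_mean(np.full((4, 4, 4), 2.5), m) == 2.5

    def test_single_voxel(self, rng):
        v = rng.normal(size=(4, 4, 4))
        m = np.zeros((4, 4, 4), bool)
        m[2, 3, 1] = True
        assert roi_mean(v, m) == v[2, 3, 1]

    def test_matches_loop_oracle(self, rng):
        v = rng.normal(size=(5, 5, 5))
        m = rng.random((5, 5, 5)) > 0.5
        total = n = 0.0
        for idx in np.ndindex(v.shape):
            if m[idx]:
                total += v[idx]
                n += 1
        assert roi_mean(v, m) == pytest.approx(total / n, abs=1e-12)

    def test_empty_mask_error(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestGroupOneSample:
    def test_matches_closed_form(self, rng):
        cons = rng.normal(0.5, 1.0, size=(30, 50))
        t, df, flag = group_onesample(cons)
        expect = cons.mean(0) / (cons.std(0, ddof=1) / np.sqrt(30))
        assert np.max(np.abs(t - expect)) <= 1e-10
        assert df == 29
        assert not flag.any()

    def test_sign_symmetric_maps_give_zero(self, rng):
        v = rng.normal(size=(10, 20))
        cons = np.vstack([v, -v])
        t, _, _ = group_onesample(cons)
        assert np.allclose(t, 0.0, atol=1e-10)

    def test_null_calibration_at_p001(self):
        """Fraction of null |t| values beyond the two-sided p < 0.001
        threshold is ~0.001 within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        n, reps = 20, 40
        exceed = total = 0
        thr = sps.t.ppf(1 - 0.0005, n - 1)
        for _ in range(reps):
            t, _, _ = group_onesample(rng.normal(size=(n, 5000)))
            exceed += int((np.abs(t) > thr).sum())
            total += t.size
        rate = exceed / total
        se = np.sqrt(0.001 * 0.999 / total)
        assert abs(rate - 0.001) < 4 * se

    def test_zero_variance_flagged_infinite(self):
        cons = np.ones((5, 3))
        cons[:, 1] = -2.0
        cons[:, 2] = 0.0
        t, _, flag = group_onesample(cons)
        assert t[0] == np.inf and t[1] == -np.inf and t[2] == 0.0
        assert flag.all()


class TestClusterFwe:
    def test_identity_flip_bounds_p(self, rng):
        """The observed statistic is its own permutation, so corrected
        p >= 1/(n_perm+1)."""
        cons = rng.normal(0.0, 1.0, size=(12, 4 ** 3)) + 1.5
        tab = cluster_fwe(cons, (4, 4, 4), n_perm=100, seed=1)
        assert len(tab) >= 1
        assert (tab["p_fwe"] >= 1.0 / 101).all()

    def test_planted_blob_detected(self):
        """A strong planted blob survives FWE 0.05 in every seeded run."""
        shape = (8, 8, 8)
        blob = np.zeros(shape)
        blob[2:6, 2:6, 2:6] = 1.5
        hits = 0
        n_rep = 10
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            cons = rng.normal(size=(15, 512)) + blob.ravel()
            tab = cluster_fwe(cons, shape, n_perm=200, seed=s)
            hits += bool(len(tab)) and tab["p_fwe"].min() <= 0.05
        assert hits == n_rep

    def test_no_suprathreshold_voxels_empty_table(self):
        cons = np.zeros((8, 27)) + np.random.default_rng(3).normal(
            0, 1e-3, size=(8, 27))
        tab = cluster_fwe(cons, (3, 3, 3), n_perm=100, seed=0,
                          voxel_p=1e-9)
        assert len(tab) == 0

    def test_min_permutations_enforced(self, rng):
        with pytest.raises(ValueError, match="100"):
            cluster_fwe(rng.normal(size=(8, 27)), (3, 3, 3), n_perm=50)
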