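"""GLM machinery: HRF, designs, first-level/group fits, clusters, ROIs."""

import numpy as np
import pytest
import scipy.stats as st

from nfsim.glm import (StatMap, build_design, canonical_hrf,
                       cluster_threshold, convolve_with_hrf,
                       fit_first_level, group_covariate, group_one_sample,
                       roi_summary, sticks_from_trs)


class TestCanonicalHrf:
    def test_peak_between_4_and_7_seconds(self):
        dt = 0.1
        h = canonical_hrf(dt)
        assert 4.0 <= np.argmax(h) * dt <= 7.0

    def test_post_peak_undershoot(self):
        h = canonical_hrf(0.5)
        assert h.min() < 0
        assert np.argmin(h) > np.argmax(h)

    def test_sampling_invariance(self):
        coarse = canonical_hrf(2.0)
        fine = canonical_hrf(1.0)
        np.testing.assert_allclose(coarse, fine[::2], atol=1e-12)

    def test_unit_peak(self):
        assert canonical_hrf(0.2).max() == pytest.approx(1.0)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestBuildDesign:
    def test_empty_event_regressor_rejected_by_rank_check(self):
        box = np.zeros(100)
        with pytest.raises(ValueError, match="all-zero"):
            build_design({"events": box}, tr_s=2.0)

    def test_block_column_matches_direct_summation_oracle(self):
        n = 60
        box = np.zeros(n)
        box[5:20] = 1.0               # one 30 s block at TR 2 s
        design = build_design({"block": box}, tr_s=2.0)
        hrf = canonical_hrf(2.0)
        oracle = np.zeros(n)
        for t in range(n):
            for k in range(len(hrf)):
                if 0 <= t - k < n:
                    oracle[t] += hrf[k] * box[t - k]
        col = design.matrix[:, design.names.index("block")]
        assert np.max(np.abs(col - oracle)) < 1e-9

    def test_disjoint_event_sets_are_not_collinear(self):
        n = 80
        a = sticks_from_trs(range(10, 40, 4), n)
        b = sticks_from_trs(range(12, 42, 4), n)
        design = build_design({"a": a, "b": b}, tr_s=2.0)
        ca = design.matrix[:, 0]
        cb = design.matrix[:, 1]
        corr = np.corrcoef(ca, cb)[0, 1]
        assert abs(corr) < 1.0 - 1e-6

    def test_event_index_outside_run_rejected(self):
        with pytest.raises(ValueError):
            sticks_from_trs([120], 100)


class TestFirstLevel:
    def _design(self, n=80):
        box = np.zeros(n)
        box[10:25] = 1
        box[40:55] = 1
        return build_design({"task": box}, tr_s=2.0)

    def test_noiseless_planted_beta_recovered_exactly(self):
        design = self._design()
        X = design.matrix
        beta_true = np.array([1.7, 0.3, -0.2])
        data = (X @ beta_true).reshape(1, 1, 1, -1) * np.ones((2, 2, 2, 1))
        cmap = fit_first_level(data, design, np.array([1.0]))
        assert np.max(np.abs(cmap - 1.7)) < 1e-9

    def test_residuals_orthogonal_to_design(self, rng):
        design = self._design()
        X = design.matrix
        data = rng.normal(size=(3, 3, 2, X.shape[0]))
        Y = data.reshape(-1, X.shape[0]).T
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_contrast_on_equal_betas_is_zero(self):
        n = 80
        a = sticks_from_trs(range(10, 40, 6), n)
        b = sticks_from_trs(range(12, 42, 6), n)
        design = build_design({"a": a, "b": b}, tr_s=2.0)
        X = design.matrix
        # equal planted effects on both regressors
        data = (X @ np.array([2.0, 2.0, 0.5, 0.1]))[None, None, None, :]
        cmap = fit_first_level(data, design, np.array([1.0, -1.0]))
        assert np.max(np.abs(cmap)) < 1e-9

    def test_beta_sampling_variance_matches_analytic_ols(self, rng):
        """Empirical SD of the contrast across replicates vs (X'X)^-1."""
        design = self._design(60)
        X = design.matrix
        c = np.array([1.0, 0.0, 0.0])
        sigma = 1.3
        analytic = sigma * np.sqrt(c @ np.linalg.inv(X.T @ X) @ c)
        n_rep = 500
        data = rng.normal(0, sigma, size=(n_rep, 1, 1, X.shape[0]))
        vals = [fit_first_level(data[i][None], design, c)[0, 0, 0]
                for i in range(n_rep)]
        assert np.std(vals) == pytest.approx(analytic, rel=0.10)

    def test_design_row_mismatch_rejected(self, rng):
        design = self._design(80)
        with pytest.raises(ValueError):
            fit_first_level(rng.normal(size=(2, 2, 2, 50)), design,
                            np.array([1.0]))


class TestGroupOneSample:
    def test_identical_maps_yield_undefined_marker(self):
        maps = [np.ones((4, 4, 2))] * 5
        out = group_one_sample(maps)
        assert np.all(np.isnan(out.t))
        assert out.df == 4

    def test_null_t_values_follow_t_distribution(self, rng):
        n = 8
        maps = rng.normal(size=(n, 25, 25, 16))
        out = group_one_sample(list(maps))
        tvals = out.t.ravel()
        ks = st.kstest(tvals, st.t(df=n - 1).cdf)
        assert ks.pvalue > 0.01

    def test_detection_rate_matches_noncentral_t_power(self, rng):
        """Planted group mean: empirical hit rate vs analytic power."""
        n, delta, sigma, alpha = 12, 1.0, 1.5, 0.05
        thr = st.t.isf(alpha, n - 1)
        ncp = delta / (sigma / np.sqrt(n))
        power = st.nct(df=n - 1, nc=ncp).sf(thr)
        maps = delta + rng.normal(0, sigma, size=(n, 20, 20, 10))
        out = group_one_sample(list(maps))
        rate = np.mean(out.t > thr)
        se = np.sqrt(power * (1 - power) / out.t.size)
        assert abs(rate - power) < 4 * se


class TestGroupCovariate:
    def test_orthogonal_covariate_gives_centered_t(self, rng):
        n = 14
        maps = list(rng.normal(size=(n, 10, 10, 6)))
        d = rng.normal(size=n)
        c = rng.normal(size=n)
        out = group_covariate(maps, d, c)
        assert out.df == n - 3
        t_se = st.t(df=n - 3).std() / np.sqrt(out.t.size)
        assert abs(np.nanmean(out.t)) < 4 * t_se
        ks = st.kstest(out.t.ravel(), st.t(df=n - 3).cdf)
        assert ks.pvalue > 0.01

    def test_constant_control_equals_two_column_fit(self, rng):
        n = 10
        maps = list(rng.normal(size=(n, 6, 6, 4)))
        d = rng.normal(size=n)
        out3 = group_covariate(maps, d, np.full(n, 7.0))
        # two-column oracle fit
        X = np.column_stack([np.ones(n), d])
        Y = np.stack(maps).reshape(n, -1)
        beta = np.linalg.pinv(X) @ Y
        resid = Y - X @ beta
        s2 = (resid ** 2).sum(axis=0) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        np.testing.assert_allclose(out3.t.ravel(), beta[1] / se,
                                   atol=1e-10)
        assert out3.df == n - 2

    def test_collinear_covariates_rejected(self, rng):
        maps = list(rng.normal(size=(8, 4, 4, 2)))
        d = rng.normal(size=8)
        with pytest.raises(ValueError):
            group_covariate(maps, d, 2.0 * d)

    def test_effect_via_control_keeps_improvement_null(self, rng):
        """Signal carried by the control covariate: the improvement
        coefficient rejects at the nominal rate."""
        n, reps = 16, 60
        hits, total = 0, 0
        for _ in range(reps):
            c = rng.normal(size=n)
            d = rng.normal(size=n)
            maps = [ci * np.ones((6, 6, 4)) + rng.normal(0, 1, (6, 6, 4))
                    for ci in c]
            out = group_covariate(maps, d, c)
            thr = st.t.isf(0.05, out.df)
            hits += np.sum(out.t > thr)
            total += out.t.size
        rate = hits / total
        assert abs(rate - 0.05) < 0.015


class TestClusterThreshold:
    def _map(self, t, df=15):
        return StatMap(t=t, df=df, model="one_sample")

    def test_single_voxel_below_extent_dropped(self):
        t = np.zeros((8, 8, 4))
        t[2, 2, 2] = 10.0
        table = cluster_threshold(self._map(t), k=2)
        assert len(table) == 0

    def test_blob_of_27_survives_k15(self):
        t = np.zeros((9, 9, 9))
        t[3:6, 3:6, 3:6] = 8.0
        table = cluster_threshold(self._map(t), k=15)
        assert len(table) == 1
        assert table.clusters.iloc[0].size_voxels == 27
        assert table.clusters.iloc[0].peak_t == pytest.approx(8.0)

    def test_edge_joined_blobs_split_under_face_connectivity(self):
        t = np.zeros((10, 10, 4))
        t[2:4, 2:4, 1] = 9.0
        t[4:6, 4:6, 1] = 9.0          # touches only along an edge
        table = cluster_threshold(self._map(t), k=1)
        assert len(table) == 2

    def test_output_invariant_to_axis_flips(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(12, 12, 6)) + 2.0
        a = cluster_threshold(self._map(t), k=3)
        b = cluster_threshold(self._map(t[::-1].copy()), k=3)
        assert sorted(a.clusters.size_voxels) == \
            sorted(b.clusters.size_voxels)

    def test_two_sided_option_catches_negative_clusters(self):
        t = np.zeros((8, 8, 4))
        t[1:4, 1:4, 1:3] = -9.0
        assert len(cluster_threshold(self._map(t), k=5)) == 0
        assert len(cluster_threshold(self._map(t), k=5,
                                     two_sided=True)) == 1


class TestRoiSummary:
    def test_monotone_roi_means_give_rho_one(self):
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[1:3, 1:3, :] = True
        maps = [i * np.ones((4, 4, 2)) for i in range(6)]
        d = np.arange(6, dtype=float)
        means, res = roi_summary(maps, mask, d)
        np.testing.assert_allclose(means, d)
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        maps = [i * np.ones((2, 2, 1)) for i in range(5)]
        _, res = roi_summary(maps, mask, -np.arange(5.0))
        assert res.statistic == pytest.approx(-1.0)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            roi_summary([np.ones((2, 2, 1))] * 3,
                        np.zeros((2, 2, 1), bool), [1, 2, 3])
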