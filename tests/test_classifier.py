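"""Decoder training, preprocessing contracts, and held-out evaluation."""

import numpy as np
import pytest

from nfsim.classifier import (ClassifierModel, decode, evaluate_held_out,
                              gaussian_blur, labels_from_schedule,
                              offline_preprocess, online_preprocess,
                              replay_run_online,
                              task_regressor_from_schedule,
                              train_classifier)
from nfsim.synthetic import (SessionConfig, VolumeSeries,
                             generate_session, generate_tapping_schedule)


class TestOfflinePreprocess:
    def test_zero_nuisance_input_blurred_with_zero_mean_residual(self, rng):
        data = rng.normal(size=(6, 6, 4, 40))
        run = VolumeSeries(data=data, tr_s=2.0, run_index=1)
        out = offline_preprocess(run, np.zeros((40, 6)),
                                 blur_fwhm_voxels=1.5)
        oracle = gaussian_blur(
            (data - data.mean(axis=3, keepdims=True)
             ).reshape(-1, 40).T.reshape(40, 6, 6, 4)
            .transpose(1, 2, 3, 0), 0)  # mean-removal check only
        assert np.max(np.abs(out.data.mean(axis=3))) < 1e-10
        assert oracle.shape == out.data.shape

    def test_planted_slope_removed(self):
        t = np.arange(60, dtype=float)
        slopes = np.linspace(-1, 1, 24).reshape(2, 3, 4)
        data = 10 + slopes[..., None] * t
        run = VolumeSeries(data=data, tr_s=2.0, run_index=1)
        out = offline_preprocess(run, None, blur_fwhm_voxels=0.0)
        # least-squares slope of the residuals
        tc = t - t.mean()
        resid_slopes = out.data @ tc / (tc @ tc)
        assert np.max(np.abs(resid_slopes)) < 1e-8

    def test_blur_kernel_fwhm_matches_configuration(self):
        impulse = np.zeros((33, 33, 33))
        impulse[16, 16, 16] = 1.0
        fwhm = 3.0
        blurred = gaussian_blur(impulse, fwhm)
        profile = blurred[:, 16, 16]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        width = above[-1] - above[0] + 1
        assert abs(width - fwhm) <= 1.0  # half a voxel per side

    def test_duplicated_motion_series_rejected(self, rng):
        data = rng.normal(size=(4, 4, 2, 30))
        run = VolumeSeries(data=data, tr_s=2.0, run_index=1)
        m = np.tile(rng.normal(size=(30, 1)), (1, 6))   # six copies
        with pytest.raises(ValueError, match="singular"):
            offline_preprocess(run, m)


class TestOnlinePreprocess:
    def test_history_trend_extrapolates_to_zero_residual(self):
        shape = (4, 4, 2)
        slopes = np.linspace(0.5, 2.0, 32).reshape(shape)
        t = np.arange(31, dtype=float)
        series = slopes[..., None] * t
        out = online_preprocess(series[..., 30], None, series[..., :30],
                                None, blur_fwhm_voxels=0.0)
        assert np.max(np.abs(out)) < 1e-8

    def test_empty_history_is_passthrough(self, rng):
        vol = rng.normal(size=(4, 4, 2))
        out = online_preprocess(vol, None, None, None,
                                blur_fwhm_voxels=0.0)
        np.testing.assert_array_equal(out, vol)

    def test_short_history_centers_on_history_mean(self, rng):
        series = rng.normal(size=(4, 4, 2, 5))
        vol = rng.normal(size=(4, 4, 2))
        out = online_preprocess(vol, None, series, None,
                                blur_fwhm_voxels=0.0)
        np.testing.assert_allclose(out, vol - series.mean(axis=-1))

    def test_online_converges_to_offline_on_nuisance_span_data(self, rng):
        """Noiseless data inside the nuisance span: both the offline
        projection and the history-extrapolation residual vanish, so
        their gap is tiny once the history is long."""
        n = 210
        t = np.arange(n, dtype=float)
        motion = rng.normal(size=(n, 6)).cumsum(axis=0)
        shape = (3, 3, 2)
        coeffs = rng.normal(size=shape + (8,))
        X = np.column_stack([np.ones(n), t, motion])
        data = np.einsum("xyzk,tk->xyzt", coeffs, X)
        run = VolumeSeries(data=data, tr_s=2.0, run_index=1)
        off = offline_preprocess(run, motion, blur_fwhm_voxels=0.0)
        t_idx = 200
        on = online_preprocess(data[..., t_idx], motion[t_idx],
                               data[..., :t_idx], motion[:t_idx],
                               blur_fwhm_voxels=0.0)
        gap = np.abs(on - off.data[..., t_idx])
        assert gap.max() < 1e-6


class TestTraining:
    def _toy_model(self, rng):
        schedule = generate_tapping_schedule(0)
        n = schedule.n_trs
        shape = (6, 6, 4)
        brain = np.ones(shape, bool)
        visual = np.zeros(shape, bool)
        visual[:, 4:, :] = True
        from nfsim.synthetic import MaskSet
        masks = MaskSet(brain_mask=brain, visual_exclusion_mask=visual,
                        analysis_mask=brain & ~visual)
        labels = labels_from_schedule(schedule, 0)
        sig = np.array([1.0 if l == "tap" else -1.0 for l in labels])
        data = rng.normal(size=shape + (n,)) * 0.01
        data[1, 1, 1] += 5 * sig        # separable single-voxel signal
        run = VolumeSeries(data=data, tr_s=2.0, run_index=1)
        return run, schedule, masks

    def test_separable_classes_reach_zero_training_error(self, rng):
        run, schedule, masks = self._toy_model(rng)
        model = train_classifier([run], [schedule], masks,
                                 label_shift_trs=0)
        labels = labels_from_schedule(schedule, 0)
        preds = [decode(model, run.data[..., t]).label
                 for t in range(run.n_trs)]
        assert all(p == l for p, l in zip(preds, labels) if l)

    def test_visual_exclusion_voxels_carry_zero_weight(self, trained_model):
        visual = trained_model.masks.visual_exclusion_mask
        assert np.all(trained_model.weights[visual] == 0)

    def test_training_invariant_to_voxels_outside_mask(self, rng):
        run, schedule, masks = self._toy_model(rng)
        model_a = train_classifier([run], [schedule], masks,
                                   label_shift_trs=0)
        perturbed = run.data.copy()
        perturbed[~masks.analysis_mask] += rng.normal(
            size=perturbed[~masks.analysis_mask].shape) * 50
        run_b = VolumeSeries(data=perturbed, tr_s=2.0, run_index=1)
        model_b = train_classifier([run_b], [schedule], masks,
                                   label_shift_trs=0)
        np.testing.assert_allclose(model_a.weights, model_b.weights)
        assert model_a.bias == pytest.approx(model_b.bias)

    def test_single_class_labels_rejected(self, rng):
        run, schedule, masks = self._toy_model(rng)
        # shift so large every label becomes None except one class
        with pytest.raises(ValueError):
            train_classifier([run], [schedule], masks,
                             label_shift_trs=10_000)


class TestDecode:
    def _model(self, shape=(3, 3, 2)):
        from nfsim.synthetic import MaskSet
        brain = np.ones(shape, bool)
        masks = MaskSet(brain_mask=brain,
                        visual_exclusion_mask=np.zeros(shape, bool),
                        analysis_mask=brain)
        w = np.zeros(shape)
        w[0, 0, 0], w[1, 1, 1] = 2.0, -1.0
        return ClassifierModel(weights=w, bias=0.5, masks=masks)

    def test_value_matches_hand_dot_product(self):
        model = self._model()
        x = np.zeros((3, 3, 2))
        x[0, 0, 0], x[1, 1, 1] = 3.0, 4.0
        d = decode(model, x)
        assert d.decision_value == pytest.approx(2 * 3 - 1 * 4 + 0.5)
        assert d.label == "tap"

    def test_zero_value_ties_to_rest(self):
        model = self._model()
        x = np.zeros((3, 3, 2))
        x[0, 0, 0] = -0.25              # w.x = -0.5 cancels bias
        d = decode(model, x)
        assert d.decision_value == pytest.approx(0.0)
        assert d.label == "rest"

    def test_linearity_under_negation(self):
        model = self._model()
        model.bias = 0.0
        x = np.random.default_rng(0).normal(size=(3, 3, 2))
        a = decode(model, x).decision_value
        b = decode(model, -x).decision_value
        assert a == pytest.approx(-b)

    def test_grid_mismatch_rejected(self):
        model = self._model()
        with pytest.raises(ValueError):
            decode(model, np.zeros((4, 4, 2)))


class TestHeldOut:
    def test_noiseless_planted_session_decodes_near_ceiling(
            self, quiet_session):
        """Without noise the only losses are the whole-TR ambiguity of
        the hemodynamic ramp at block boundaries (~1 TR per transition);
        every within-block TR must decode correctly."""
        s = quiet_session
        pre = [offline_preprocess(
            s.runs[r][0], s.truth.motion_params[r],
            task_regressor=task_regressor_from_schedule(s.runs[r][1]))
            for r in (1, 2)]
        model = train_classifier(pre, [s.runs[r][1] for r in (1, 2)],
                                 s.masks)
        acc = evaluate_held_out(
            model, [s.runs[r][0] for r in (5, 6)],
            [s.runs[r][1] for r in (5, 6)],
            [s.truth.motion_params[r] for r in (5, 6)])
        assert acc["overall_accuracy"] >= 0.9

    def test_label_shuffled_null_sits_at_chance(self, default_session,
                                                trained_model, rng):
        s = default_session
        run, schedule = s.runs[5]
        decisions = replay_run_online(trained_model, run,
                                      s.truth.motion_params[5],
                                      schedule=schedule)
        labels = np.array([l for l in labels_from_schedule(schedule)
                           if l is not None])
        preds = np.array([d.label for d in decisions[2:]])
        accs = []
        for _ in range(60):
            accs.append(np.mean(preds == rng.permutation(labels)))
        assert abs(np.mean(accs) - 0.5) < 0.03

    def test_decoding_deterministic(self, default_session, trained_model):
        s = default_session
        run = s.runs[5][0]
        a = replay_run_online(trained_model, run, s.truth.motion_params[5],
                              schedule=s.runs[5][1])
        b = replay_run_online(trained_model, run, s.truth.motion_params[5],
                              schedule=s.runs[5][1])
        assert [d.decision_value for d in a] == \
            [d.decision_value for d in b]

    def test_accuracy_monotone_in_planted_amplitude(self):
        """Held-out accuracy does not degrade as the planted tapping
        amplitude grows (trend over three levels, two seeds each)."""
        means = []
        for amp in (0.5, 2.0, 6.0):
            accs = []
            for seed in (21, 22):
                cfg = SessionConfig(tap_amplitude=amp)
                s = generate_session(0, seed=seed, config=cfg)
                pre = [offline_preprocess(
                    s.runs[r][0], s.truth.motion_params[r],
                    task_regressor=task_regressor_from_schedule(
                        s.runs[r][1]))
                    for r in (1, 2)]
                model = train_classifier(pre,
                                         [s.runs[r][1] for r in (1, 2)],
                                         s.masks)
                acc = evaluate_held_out(
                    model, [s.runs[r][0] for r in (5, 6)],
                    [s.runs[r][1] for r in (5, 6)],
                    [s.truth.motion_params[r] for r in (5, 6)])
                accs.append(acc["overall_accuracy"])
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.02
        assert means[1] <= means[2] + 0.02
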