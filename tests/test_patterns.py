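"""Pattern statistics: scalar responses, templates, decoding, ROC, ROI ops."""

import numpy as np
import pytest

from pupilbias import patterns
from pupilbias.patterns import PatternSet, ROIResponseSet


def _noise_patterns(n_trials=100, n_voxels=60, seed=0, orient_amp=0.0,
                    choice_amp=0.0):
    rng = np.random.default_rng(seed)
    half = n_voxels // 2
    stim = rng.integers(0, 2, n_trials)
    choice = rng.integers(0, 2, n_trials)
    orient = np.where(rng.integers(0, 2, n_trials) == 1, "CCW", "CW")
    w_o = rng.normal(0, 1, n_voxels)
    w_c = np.concatenate([rng.normal(0, 1, half)] * 2) * \
        np.concatenate([np.ones(half), -np.ones(half)])
    X = rng.normal(0, 1.0, (n_trials, n_voxels))
    X += orient_amp * (np.where(orient == "CCW", 1.0, -1.0) * stim)[:, None] * w_o
    X += choice_amp * (2.0 * choice - 1.0)[:, None] * w_c
    coords_half = rng.uniform(0, 30, (half, 3))
    return PatternSet(
        responses=X, stimulus=stim, choice=choice, block_orientation=orient,
        hemisphere=np.array(["L"] * half + ["R"] * half),
        homotopic_partner=np.concatenate([np.arange(half, n_voxels),
                                          np.arange(half)]),
        coords=np.vstack([coords_half * [-1, 1, 1], coords_half]),
    )


class TestScalarResponse:
    def test_flat_epoch_gives_zero(self):
        times = np.arange(-2, 14, 2.0)
        assert patterns.trial_scalar_response(np.ones(times.size), times) == 0.0

    def test_boxcar_height_recovered(self):
        times = np.arange(-1.75, 13.8, 0.5)  # grid avoids the shared t=2 edge
        epoch = np.where(times > 2, 3.0, 0.0)
        assert patterns.trial_scalar_response(epoch, times) == pytest.approx(3.0)

    def test_response_monotone_in_injected_amplitude(self):
        times = np.arange(-2, 14, 0.5)
        hrf = np.clip(np.sin((times - 2) / 10 * np.pi), 0, None)
        vals = [patterns.trial_scalar_response(a * hrf, times)
                for a in (0.5, 1.0, 2.0)]
        assert vals[0] < vals[1] < vals[2]


class TestVoxelTstat:
    def test_matches_hand_computed_toy(self):
        # 6 trials, 1 voxel: CW = [1, 2, 3], CCW = [4, 5, 6]
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        cw = np.array([1, 1, 1, 0, 0, 0], bool)
        t = patterns.voxel_tstat(X, cw, ~cw)[0]
        sem = np.std([1, 2, 3], ddof=1) / np.sqrt(3)
        assert t == pytest.approx((2.0 - 5.0) / np.sqrt(2 * sem**2))

    def test_strong_voxel_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 20))
        cond = np.arange(40) < 20
        X[cond, 7] += 5.0
        t = patterns.voxel_tstat(X, cond, ~cond)
        assert np.argmax(t) == 7

    def test_selection_is_deterministic_under_ties(self):
        t = np.zeros(10)
        sel1 = patterns.select_voxels(t, n_each=2)
        sel2 = patterns.select_voxels(t, n_each=2)
        assert np.array_equal(sel1, sel2)


class TestTemplateResponse:
    def test_pure_noise_scores_are_chance(self):
        pset = _noise_patterns(seed=1)
        scores = patterns.template_response(pset, mode="orientation", n_each=10)
        idx = patterns.roc_predictive_index(scores, pset.stimulus,
                                            balance_by=pset.choice)
        assert idx == pytest.approx(0.5, abs=0.12)

    def test_exact_template_patterns_score_plus_minus_one(self):
        rng = np.random.default_rng(2)
        n_vox = 20
        tmpl = rng.normal(0, 1, n_vox)
        n = 40
        choice = np.tile([1, 0], n // 2)
        X = np.where(choice[:, None] == 1, tmpl, -tmpl)
        pset = PatternSet(responses=X, stimulus=np.ones(n, int), choice=choice,
                          block_orientation=np.array(["CW"] * n))
        scores = patterns.template_response(pset, mode="choice", n_each=n_vox // 2)
        assert np.allclose(np.abs(scores), 1.0, atol=1e-10)
        assert np.all(np.sign(scores) == np.where(choice == 1, 1, -1))

    def test_orientation_score_increases_with_amplitude(self):
        # scores share templates across trials, so average over datasets
        means = []
        for amp in (0.0, 0.2, 0.5):
            diffs = []
            for seed in (3, 4, 5):
                pset = _noise_patterns(seed=seed, orient_amp=amp)
                scores = patterns.template_response(pset, mode="orientation",
                                                    n_each=10)
                sig = pset.stimulus == 1
                diffs.append(scores[sig].mean() - scores[~sig].mean())
            means.append(np.mean(diffs))
        assert means[0] < means[1] < means[2]

    def test_single_condition_fold_rejected(self):
        pset = _noise_patterns(n_trials=10, seed=4)
        pset.stimulus[:] = 1
        pset.block_orientation[:] = "CW"
        with pytest.raises(ValueError, match="single condition"):
            patterns.template_response(pset, mode="orientation", n_each=5)


class TestChoiceLogistic:
    def test_uninformative_voxels_have_null_slopes(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (300, 10))
        y = rng.integers(0, 2, 300)
        fit = patterns.choice_logistic(X, y)
        assert np.mean(np.abs(fit.beta1)) < 0.3

    def test_informative_voxel_has_positive_slope(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 400)
        X = (2.0 * y - 1.0)[:, None] + rng.normal(0, 1, (400, 1))
        fit = patterns.choice_logistic(X, y)
        assert fit.beta1[0] > 0.5

    def test_logistic_scale_equivariance(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 400)
        X = (2.0 * y - 1.0)[:, None] + rng.normal(0, 1.5, (400, 1))
        b1 = patterns.choice_logistic(X, y).beta1[0]
        b1_scaled = patterns.choice_logistic(2.0 * X, y).beta1[0]
        assert b1_scaled == pytest.approx(b1 / 2.0, rel=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.tile([0, 1], 20)
        X = (2.0 * y - 1.0)[:, None] * 10.0
        fit = patterns.choice_logistic(X, y)
        assert fit.separation_flagged[0]


class TestLateralize:
    def test_symmetric_bilateral_pattern_has_zero_lateralization(self):
        pset = _noise_patterns(seed=8)
        X = pset.responses
        pset.responses = (X + X[:, pset.homotopic_partner]) / 2  # symmetric part
        lat = patterns.lateralize(pset, yes_hand="left")
        assert np.allclose(lat, 0.0, atol=1e-12)

    def test_double_flip_is_identity(self):
        pset = _noise_patterns(seed=9)
        partner = pset.homotopic_partner
        flipped_twice = pset.responses[:, partner][:, partner]
        assert np.array_equal(flipped_twice, pset.responses)

    def test_mirror_subjects_yield_identical_lateralization(self):
        """A subject with the opposite response mapping and mirrored activity
        must produce the same lateralization map after the hemisphere flip."""
        pset = _noise_patterns(seed=10)
        lat_left = patterns.lateralize(pset, yes_hand="left")
        mirrored = _noise_patterns(seed=10)
        mirrored.responses = pset.responses[:, pset.homotopic_partner]
        lat_right = patterns.lateralize(mirrored, yes_hand="right")
        assert np.allclose(lat_left, lat_right)


class TestSearchlight:
    def test_shuffled_labels_give_chance_map(self):
        pset = _noise_patterns(n_trials=40, n_voxels=30, seed=11)
        scores = patterns.searchlight_choice(pset, radius_mm=15.0,
                                             centers=[0, 5, 10])
        ok = np.isfinite(scores)
        assert np.all(np.abs(scores[ok] - 0.5) < 0.35)
        assert np.nanmean(np.abs(scores[ok] - 0.5)) < 0.2

    def test_informative_cluster_peaks_at_cluster(self):
        rng = np.random.default_rng(12)
        n, n_vox = 60, 40
        coords = rng.uniform(0, 100, (n_vox, 3))
        coords[:5] = coords[0] + rng.uniform(-3, 3, (5, 3))  # tight cluster
        choice = rng.integers(0, 2, n)
        X = rng.normal(0, 1, (n, n_vox))
        X[:, :5] += 2.5 * (2 * choice - 1)[:, None]
        pset = PatternSet(responses=X, stimulus=np.zeros(n, int), choice=choice,
                          block_orientation=np.array(["CW"] * n), coords=coords)
        scores = patterns.searchlight_choice(pset, radius_mm=8.0)
        assert np.nanargmax(scores) < 5

    def test_loo_scheme_is_deterministic(self):
        pset = _noise_patterns(n_trials=30, n_voxels=20, seed=13)
        a = patterns.searchlight_choice(pset, radius_mm=20.0, centers=[0, 3])
        b = patterns.searchlight_choice(pset, radius_mm=20.0, centers=[0, 3])
        assert np.array_equal(a[np.isfinite(a)], b[np.isfinite(b)])


class TestROCIndex:
    def test_identical_scores_give_half(self):
        scores = np.ones(40)
        labels = np.tile([0, 1], 20)
        assert patterns.roc_predictive_index(scores, labels) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        scores = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert patterns.roc_predictive_index(scores, labels) == 1.0

    def test_equals_mann_whitney_statistic(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(0, 1, 10)
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0])
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = u / (len(pos) * len(neg))
        assert patterns.roc_predictive_index(scores, labels) == \
            pytest.approx(expected)

    def test_balancing_removes_confound(self):
        """Scores driven purely by choice must be at chance for predicting
        the stimulus once balanced within choice."""
        rng = np.random.default_rng(15)
        n = 2000
        choice = rng.integers(0, 2, n)
        stim = np.where(rng.random(n) < 0.8, choice, 1 - choice)
        scores = choice + rng.normal(0, 0.1, n)
        raw = patterns.roc_predictive_index(scores, stim)
        balanced = patterns.roc_predictive_index(scores, stim, balance_by=choice)
        assert raw > 0.7
        assert balanced == pytest.approx(0.5, abs=0.05)


class TestCombineAndCorrelate:
    def test_single_roi_combined_signal_is_zscored_roi(self):
        rng = np.random.default_rng(16)
        x = rng.normal(3, 2, (200, 1))
        target = x[:, 0] + rng.normal(0, 1, 200)
        _, combined = patterns.combine_signals(x, target)
        assert np.allclose(combined, (x[:, 0] - x[:, 0].mean()) / x[:, 0].std())

    def test_combined_signal_beats_single_rois_in_sample(self):
        rng = np.random.default_rng(17)
        X = rng.normal(0, 1, (300, 3))
        target = X @ np.array([0.5, 0.3, 0.0]) + rng.normal(0, 1, 300)
        _, combined = patterns.combine_signals(X, target)
        r_comb = np.corrcoef(combined, target)[0, 1]
        r_single = max(abs(np.corrcoef(X[:, j], target)[0, 1]) for j in range(3))
        assert r_comb >= r_single - 1e-12

    def test_partial_correlation_two_routes_agree(self):
        """Residual-correlation partial r must equal the inverse-covariance
        (precision matrix) definition."""
        rng = np.random.default_rng(18)
        n = 500
        tpr = rng.normal(0, 1, n)
        X = np.column_stack([0.5 * tpr + rng.normal(0, 1, n),
                             0.2 * tpr + rng.normal(0, 1, n),
                             rng.normal(0, 1, n)])
        roi = ROIResponseSet(responses=X, roi_names=["a", "b", "c"], tpr=tpr)
        out = patterns.tpr_brainstem_correlation(roi, np.zeros(n))
        # precision-matrix route over [tpr, others, roi_j]
        for j, name in enumerate(["a", "b", "c"]):
            M = np.column_stack([tpr, X])
            P = np.linalg.inv(np.cov(M.T))
            expected = -P[0, j + 1] / np.sqrt(P[0, 0] * P[j + 1, j + 1])
            assert out.loc[name, "partial_r"] == pytest.approx(expected, abs=1e-10)

    def test_bin_linear_fit_recovers_slope_and_residual_invariance(self):
        rng = np.random.default_rng(19)
        n = 2000
        tpr = rng.normal(0, 1, n)
        stim = rng.integers(0, 2, n).astype(float)
        ctx = 0.5 * tpr + rng.normal(0, 0.5, n)
        from pupilbias.pupil import residualize

        b0, b1 = patterns.bin_linear_fit(residualize(ctx, stim), tpr)
        assert b1 == pytest.approx(0.5, abs=0.1)
        ctx2 = ctx + 3.0 * stim
        b0b, b1b = patterns.bin_linear_fit(residualize(ctx2, stim), tpr)
        assert b1b == pytest.approx(b1, abs=0.05)


class TestROIMask:
    def test_retains_exactly_requested_voxels(self):
        rng = np.random.default_rng(20)
        probs = rng.random(60)
        idx, w = patterns.probability_mask(probs, n_voxels=12)
        assert idx.size == 12
        assert w.sum() == pytest.approx(1.0)
        assert set(idx) == set(np.argsort(-probs)[:12])

    def test_weighted_timeseries_uses_probability_weights(self):
        probs = np.array([0.9, 0.5, 0.1, 0.0])
        X = np.array([[1.0, 2.0, 3.0, 4.0]])
        ts = patterns.roi_timeseries(X, probs, n_voxels=2)
        assert ts[0] == pytest.approx((0.9 * 1 + 0.5 * 2) / 1.4)

    def test_errors_on_bad_input(self):
        with pytest.raises(ValueError):
            patterns.probability_mask(np.array([-0.1, 0.5]), 1)
        with pytest.raises(ValueError):
            patterns.probability_mask(np.array([0.5]), 12)
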