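"""Signal-detection metrics, balancing, polynomial regression, permutation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pupilbias import sdt


class TestSDTMetrics:
    def test_no_sensitivity_no_bias(self):
        res = sdt.sdt_metrics(50, 50, 50, 50)
        assert res.dprime == pytest.approx(0.0)
        assert res.criterion == pytest.approx(0.0)

    def test_inverse_normal_oracle(self):
        # H=0.8, F=0.3: z(0.8)=0.8416, z(0.3)=-0.5244
        res = sdt.sdt_metrics(80, 20, 30, 70)
        assert res.dprime == pytest.approx(1.366, abs=1e-3)
        assert res.criterion == pytest.approx(-0.159, abs=1e-3)

    def test_swapping_cells_negates_dprime(self):
        a = sdt.sdt_metrics(70, 30, 20, 80)
        b = sdt.sdt_metrics(30, 70, 80, 20)
        assert b.dprime == pytest.approx(-a.dprime)

    def test_degenerate_rates_edge_corrected(self):
        res = sdt.sdt_metrics(50, 0, 0, 50)
        assert np.isfinite(res.dprime) and res.hit_rate < 1.0

    def test_empty_cell_raises_with_cell_name(self):
        with pytest.raises(ValueError, match="noise"):
            sdt.sdt_metrics(10, 5, 0, 0)

    def test_recovers_equal_variance_gaussian_observer(self):
        """d' and criterion from counts recover the generating observer to
        within 0.05 at n=10^4 trials."""
        rng = np.random.default_rng(6)
        d_true, c_true = 1.2, 0.4
        n = 10000
        stim = rng.integers(0, 2, n)
        # equal-variance observer: evidence ~ N(+-d'/2, 1), criterion c
        x = rng.normal((stim - 0.5) * d_true, 1.0)
        choice = (x > c_true).astype(int)
        res = sdt.sdt_from_trials(stim, choice)
        assert res.dprime == pytest.approx(d_true, abs=0.05)
        assert res.criterion == pytest.approx(c_true, abs=0.05)


class TestBalancedFractions:
    def _trials(self, n=400, p_yes=0.7, seed=0):
        rng = np.random.default_rng(seed)
        stim = rng.integers(0, 2, n)
        choice = (rng.random(n) < p_yes).astype(int)
        bins = np.array(["low", "high"])[rng.integers(0, 2, n)]
        return stim, choice, bins

    def test_matches_plain_fraction_when_cells_balanced(self):
        stim = np.tile([1, 0], 100)
        choice = np.tile([1, 1, 0, 1], 50)
        bins = np.array(["low"] * 100 + ["high"] * 100)
        out = sdt.balanced_fraction_yes(stim, choice, bins, n_resamples=50, seed=0)
        for lbl in ("low", "high"):
            m = bins == lbl
            assert out[lbl] == pytest.approx(choice[m].mean(), abs=0.03)

    def test_stimulus_independent_choices_recover_base_rate(self):
        stim, choice, bins = self._trials(p_yes=0.7)
        out = sdt.balanced_fraction_yes(stim, choice, bins, n_resamples=300, seed=1)
        for lbl in out:
            assert out[lbl] == pytest.approx(0.7, abs=0.06)

    def test_fixed_seed_is_bit_reproducible(self):
        stim, choice, bins = self._trials()
        a = sdt.balanced_fraction_yes(stim, choice, bins, n_resamples=100, seed=3)
        b = sdt.balanced_fraction_yes(stim, choice, bins, n_resamples=100, seed=3)
        assert a == b

    def test_invariant_to_duplicating_majority_stimulus_class(self):
        stim, choice, bins = self._trials(seed=4)
        dup = stim == 1
        stim2 = np.concatenate([stim, stim[dup]])
        choice2 = np.concatenate([choice, choice[dup]])
        bins2 = np.concatenate([bins, bins[dup]])
        a = sdt.balanced_fraction_yes(stim, choice, bins, n_resamples=400, seed=5)
        b = sdt.balanced_fraction_yes(stim2, choice2, bins2, n_resamples=400, seed=5)
        for lbl in a:
            assert a[lbl] == pytest.approx(b[lbl], abs=0.05)

    def test_empty_cell_rejected(self):
        stim = np.array([1, 1, 0, 0])
        choice = np.array([1, 0, 1, 0])
        bins = np.array(["low", "low", "low", "high"])  # high bin lacks signal
        with pytest.raises(ValueError, match="empty cell"):
            sdt.balanced_fraction_yes(stim, choice, bins, n_resamples=10, seed=0)


class TestNonpreferred:
    def test_majority_choice_defines_preferred_side(self):
        rng = np.random.default_rng(7)
        stim = rng.integers(0, 2, 400)
        choice = (rng.random(400) < 0.6).astype(int)  # 60% 'yes'
        bins = np.array(["low", "high"])[rng.integers(0, 2, 400)]
        fracs, preferred = sdt.nonpreferred_fraction(stim, choice, bins,
                                                     n_resamples=100, seed=0)
        assert preferred == "yes"
        for lbl in fracs:
            assert fracs[lbl] == pytest.approx(0.4, abs=0.08)

    def test_exact_tie_prefers_yes(self):
        stim = np.tile([1, 1, 0, 0], 10)
        choice = np.tile([1, 0], 20)  # exactly 50/50
        bins = np.tile(["low", "high", "high", "low"], 10)
        _, preferred = sdt.nonpreferred_fraction(stim, choice, bins,
                                                 n_resamples=10, seed=0)
        assert preferred == "yes"

    def test_abs_criterion_invariant_to_relabeling(self):
        rng = np.random.default_rng(8)
        stim = rng.integers(0, 2, 400)
        choice = (rng.random(400) < 0.35 + 0.3 * stim).astype(int)
        bins = np.array(["low", "high"])[rng.integers(0, 2, 400)]
        a = sdt.abs_criterion(stim, choice, bins)
        b = sdt.abs_criterion(1 - stim, 1 - choice, bins)
        for lbl in a:
            assert a[lbl] == pytest.approx(b[lbl], abs=1e-10)


class TestSequentialPolyRegression:
    def test_constant_metric_selects_order_zero(self):
        Y = np.full((10, 5), 3.0) + np.random.default_rng(0).normal(0, 0.01, (10, 5))
        spec = sdt.sequential_poly_regression(Y)
        assert spec.selected_order == 0

    def test_linear_metric_selects_order_one(self):
        bins = np.arange(5.0)
        Y = np.tile(2.0 * bins, (8, 1)) + \
            np.random.default_rng(1).normal(0, 0.05, (8, 5))
        spec = sdt.sequential_poly_regression(Y, bin_values=bins)
        assert spec.selected_order == 1
        assert spec.subject_coefs.shape == (8, 2)

    def test_inverted_u_selects_order_two_in_simulation(self):
        """Quadratic ground truth (inverted U) should be detected in nearly
        all simulated cohorts at this effect size."""
        bins = np.arange(5.0)
        hits = 0
        n_cohorts = 25
        for c in range(n_cohorts):
            rng = np.random.default_rng(100 + c)
            y = 1.0 - 0.5 * (bins - 2.0) ** 2
            Y = y + rng.normal(0, 0.3, (12, 5))
            spec = sdt.sequential_poly_regression(Y, bin_values=bins)
            hits += spec.selected_order == 2
        assert hits >= int(0.9 * n_cohorts)

    def test_requires_enough_bins_and_subjects(self):
        with pytest.raises(ValueError):
            sdt.sequential_poly_regression(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            sdt.sequential_poly_regression(np.zeros((1, 5)))


class TestPairedPermutation:
    def test_identical_samples_give_p_one(self):
        a = np.arange(10.0)
        assert sdt.paired_permutation_test(a, a) == pytest.approx(1.0)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.5, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        d = a - b
        # independent brute-force enumeration of all sign patterns
        obs = abs(d.mean())
        count = 0
        for signs in itertools.product([1.0, -1.0], repeat=10):
            count += abs(np.mean(np.array(signs) * d)) >= obs - 1e-12
        expected = count / 2**10
        assert sdt.paired_permutation_test(a, b) == pytest.approx(expected)

    def test_large_consistent_difference_is_maximally_significant(self):
        rng = np.random.default_rng(10)
        b = rng.normal(0, 0.01, 14)
        a = b + 5.0
        p = sdt.paired_permutation_test(a, b)
        assert p <= 2.0 / 2**13

    def test_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.2, 1, 30)
        b = rng.normal(0.0, 1, 30)
        assert sdt.paired_permutation_test(a, b, n_perm=2000, seed=5) == \
            sdt.paired_permutation_test(a, b, n_perm=2000, seed=5)


class TestSlidingWindow:
    def test_window_count_formula(self, flat_trace, simple_table):
        stim = simple_table["stimulus"].to_numpy()
        choice = np.maximum(simple_table["choice"].to_numpy(), 0)
        starts, corrs = sdt.sliding_window_criterion(
            flat_trace, simple_table, stim, choice,
            window=0.25, step=0.025, t_start=-2.0, t_end=3.0)
        assert starts.size == int(np.floor((3.0 - (-2.0) - 0.25) / 0.025)) + 1

    def test_pupil_unrelated_to_behavior_gives_null_correlations(self):
        """With pupil fluctuations independent of choice, the TPR-criterion
        correlation time course should hover around zero."""
        import pandas as pd

        from pupilbias.preproc import PupilTrace

        rng = np.random.default_rng(12)
        n = 200
        cues = 10.0 + np.arange(n) * 12.0
        rts = rng.uniform(0.8, 3.0, n)
        table = pd.DataFrame({"trial_id": np.arange(n), "cue_time": cues,
                              "rt": rts, "choice_time": cues + rts})
        fs = 50.0
        trace = PupilTrace(rng.normal(0, 1, int((cues[-1] + 20) * fs)), fs)
        stim = rng.integers(0, 2, n)
        choice = (rng.random(n) < 0.35 + 0.3 * stim).astype(int)
        starts, corrs = sdt.sliding_window_criterion(
            trace, table, stim, choice, t_start=-2.0, t_end=2.0)
        # 5-point correlations are individually very noisy; only the average
        # level is constrained under the null
        assert abs(np.nanmean(corrs)) < 0.4

    def test_liberal_shift_with_pupil_appears_before_button_press(self):
        """When 'yes' choices are driven by the pupil level just before the
        response, the pupil-criterion correlation must be strongly negative
        in windows covering that interval."""
        import pandas as pd

        from pupilbias.preproc import PupilTrace

        rng = np.random.default_rng(13)
        n = 300
        cues = 10.0 + np.arange(n) * 12.0
        rts = rng.uniform(1.0, 3.0, n)
        table = pd.DataFrame({"trial_id": np.arange(n), "cue_time": cues,
                              "rt": rts, "choice_time": cues + rts})
        fs = 50.0
        x = rng.normal(0, 1.0, int((cues[-1] + 20) * fs))
        trace = PupilTrace(x, fs)
        stim = rng.integers(0, 2, n)
        # choice driven by mean pupil in the 0.5 s before button press
        drive = np.array([x[int((c - 0.5) * fs):int(c * fs)].mean()
                          for c in cues + rts])
        p_yes = 1.0 / (1.0 + np.exp(-(4.0 * drive + 1.0 * (stim - 0.5))))
        choice = (rng.random(n) < p_yes).astype(int)
        starts, corrs = sdt.sliding_window_criterion(
            trace, table, stim, choice, t_start=-1.0, t_end=1.0)
        pre = (starts >= -0.6) & (starts <= -0.3)
        assert np.nanmean(corrs[pre]) < -0.5
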