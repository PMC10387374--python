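"""Session statistics: exact tests, FDR, ramping, hierarchical bootstrap."""

import numpy as np
import pytest
from itertools import product
from scipy import stats as sstats

from calfads.stats import (
    NestedRates,
    benjamini_hochberg,
    classify_ramping,
    hierarchical_bootstrap,
    integration_statistic,
    recovery_time,
    task_modulated,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(a, b, alternative="two-sided"):
    """Full 2^n sign-assignment enumeration of the signed-rank null."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    diff = diff[diff != 0]
    n = diff.size
    ranks = sstats.rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    ws = np.array([np.sum(np.array(signs) * ranks) for signs in product([0, 1], repeat=n)])
    sf = np.mean(ws >= w_obs - 1e-9)
    cdf = np.mean(ws <= w_obs + 1e-9)
    if alternative == "greater":
        return w_obs, sf
    if alternative == "less":
        return w_obs, cdf
    return w_obs, min(1.0, 2.0 * min(sf, cdf))


class TestWilcoxon:
    def test_all_positive_differences_n6(self):
        a = np.arange(1.0, 7.0) + 10
        b = np.arange(1.0, 7.0)
        w, p = wilcoxon_signed_rank(a, b)
        assert np.isclose(p, 2 / 2**6)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_full_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        a = rng.normal(size=n)
        # induce ties in |differences| half of the time
        b = a - rng.choice([0.5, 1.0, -0.5, rng.normal()], size=n)
        for alt in ("two-sided", "greater", "less"):
            w, p = wilcoxon_signed_rank(a, b, alternative=alt)
            w_o, p_o = brute_force_wilcoxon(a, b, alternative=alt)
            assert np.isclose(w, w_o) and np.isclose(p, p_o), (seed, alt)

    def test_agrees_with_scipy_exact_when_tie_free(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        _, p = wilcoxon_signed_rank(a, b)
        p_scipy = sstats.wilcoxon(a, b, mode="exact").pvalue
        assert np.isclose(p, p_scipy)

    def test_large_sample_normal_approximation_reasonable(self, rng):
        a = rng.normal(size=60)
        b = a - 0.8 - rng.normal(scale=0.2, size=60)
        _, p = wilcoxon_signed_rank(a, b, alternative="greater")
        assert p < 1e-6


class TestBenjaminiHochberg:
    def brute_force_bh(self, pvals, alpha):
        p = np.asarray(pvals, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        reject = np.zeros(m, bool)
        kmax = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k / m * alpha:
                kmax = k
        reject[order[:kmax]] = True
        adj = np.empty(m)
        prev = 1.0
        for k in range(m, 0, -1):
            prev = min(prev, p[order[k - 1]] * m / k)
            adj[order[k - 1]] = prev
        return reject, adj

    def test_step_up_hand_case(self):
        reject, adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_single_pvalue_unchanged(self):
        _, adj = benjamini_hochberg([0.037])
        assert np.isclose(adj[0], 0.037)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_definitional_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(3, 40)))
        reject, adj = benjamini_hochberg(p, alpha=0.05)
        r_o, a_o = self.brute_force_bh(p, 0.05)
        np.testing.assert_array_equal(reject, r_o)
        np.testing.assert_allclose(adj, a_o, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestTaskModulated:
    def test_constant_neuron_not_modulated(self, rng):
        base = np.full((1, 20), 3.0)
        wins = np.full((1, 4, 20), 3.0)
        flags, table = task_modulated(base, wins)
        assert not flags[0]

    def test_step_neuron_modulated(self, rng):
        n_trials = 20
        base = rng.normal(3.0, 0.1, size=(2, n_trials))
        wins = rng.normal(3.0, 0.1, size=(2, 4, n_trials))
        wins[0, 1] += 5.0  # deterministic +5 Hz step in window 2, neuron 0
        flags, table = task_modulated(base, wins)
        assert flags[0] and not flags[1]

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            task_modulated(np.zeros((1, 4)), np.zeros((1, 4, 4)))


class TestRecoveryTime:
    def test_no_change_recovers_immediately(self, rng):
        base = rng.normal(5, 0.5, size=(3, 30))
        post = rng.normal(5, 0.5, size=(3, 8, 30))
        t = recovery_time(base, post)
        np.testing.assert_allclose(t, 0.0)

    def test_two_second_elevation_recovers_at_two_seconds(self, rng):
        base = rng.normal(5, 0.2, size=(4, 60))
        post = rng.normal(5, 0.2, size=(4, 8, 60))
        post[:, :4] += 4.0  # elevated for windows 0..3 (0-2 s)
        t = recovery_time(base, post, window_s=0.5)
        np.testing.assert_allclose(t, 2.0)

    def test_permanent_shift_flagged_not_recovered(self, rng):
        base = rng.normal(5, 0.2, size=(2, 40))
        post = rng.normal(9, 0.2, size=(2, 6, 40))
        t = recovery_time(base, post)
        assert np.all(np.isnan(t))

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            recovery_time(np.zeros((1, 10)), np.zeros((1, 2, 10)))


class TestClassifyRamping:
    def test_noiseless_ramp_is_up(self):
        label, slope, p = classify_ramping(np.linspace(0, 5, 40))
        assert label == "up" and slope > 0 and p < 1e-10

    def test_sign_flip_symmetry(self, rng):
        y = np.linspace(0, 3, 30) + rng.normal(scale=0.3, size=30)
        up, s_up, p_up = classify_ramping(y)
        down, s_down, p_down = classify_ramping(-y)
        assert np.isclose(s_up, -s_down) and np.isclose(p_up, p_down)
        if up == "up":
            assert down == "down"

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            classify_ramping(np.arange(5.0))


class TestHierarchicalBootstrap:
    def test_degenerate_constant_data(self):
        data = NestedRates({"s0": {"n0": np.full(10, 4.2)}})
        res = hierarchical_bootstrap(data, n_iter=50, seed=0)
        assert np.isclose(res.mean, 4.2) and res.sem == 0.0

    def test_bitwise_reproducible_given_seed(self, rng):
        data = NestedRates(
            {f"s{i}": {f"n{j}": rng.normal(size=8) for j in range(3)} for i in range(2)}
        )
        r1 = hierarchical_bootstrap(data, n_iter=30, seed=4)
        r2 = hierarchical_bootstrap(data, n_iter=30, seed=4)
        np.testing.assert_array_equal(r1.resampled_means, r2.resampled_means)

    def test_recovers_grand_mean_on_balanced_data(self):
        mu = 2.5
        deviations = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = NestedRates(
                {
                    f"s{i}": {f"n{j}": rng.normal(mu, 1.0, size=20) for j in range(4)}
                    for i in range(3)
                }
            )
            res = hierarchical_bootstrap(data, n_iter=100, seed=seed)
            deviations.append(abs(res.mean - mu) <= 3 * max(res.sem, 1e-12))
        assert np.mean(deviations) >= 0.9

    def test_empty_nesting_rejected(self):
        with pytest.raises(ValueError):
            NestedRates({})

    def test_dataframe_round_trip(self, rng):
        data = NestedRates({"s0": {"n0": rng.normal(size=5), "n1": rng.normal(size=7)}})
        back = NestedRates.from_dataframe(data.to_dataframe())
        np.testing.assert_allclose(back.values["s0"]["n0"], data.values["s0"]["n0"])


class TestIntegrationStatistic:
    def _traces(self, rng, shift, n_trials=50, noise=0.3):
        bins = 50  # 10 s at 200 ms; onset at bin 10
        arr = rng.normal(0, noise, size=(n_trials, bins))
        arr[:, 10:] += shift
        return {"s0": {"n0": arr, "n1": rng.normal(0, noise, size=(n_trials, bins)) +
                       (np.arange(bins) >= 10) * shift}}

    def test_null_data_not_significant(self, rng):
        traces = self._traces(rng, shift=0.0)
        res = integration_statistic(traces, bin_size=0.2, onset_bin=10, seed=0)
        assert res.p_one_sided > 0.05
        assert abs(res.mean) < 3 * max(res.sem, 1e-9)

    def test_sustained_shift_detected(self, rng):
        traces = self._traces(rng, shift=2.0)
        res = integration_statistic(traces, bin_size=0.2, onset_bin=10, seed=0)
        assert res.mean > 1.0
        assert res.p_one_sided < 0.05

    def test_sign_symmetry(self, rng):
        traces = self._traces(rng, shift=1.5)
        neg = {s: {n: -arr for n, arr in d.items()} for s, d in traces.items()}
        r_pos = integration_statistic(traces, bin_size=0.2, onset_bin=10, seed=0)
        r_neg = integration_statistic(neg, bin_size=0.2, onset_bin=10, seed=0)
        assert np.isclose(r_pos.mean, -r_neg.mean, atol=5 * r_pos.sem + 0.05)

    def test_short_trials_rejected(self, rng):
        traces = {"s0": {"n0": rng.normal(size=(20, 20))}}
        with pytest.raises(ValueError):
            integration_statistic(traces, bin_size=0.2, onset_bin=10)
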