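"""Spike statistics, similarity measures, FC proxy, propagation analysis."""

import numpy as np
import pytest

from mesocortex.analysis import (
    bold_proxy_fc,
    compute_rates,
    cv_isi,
    fc_similarity,
    ks_similarity,
    lvr,
    pairwise_correlations,
    perturbation_propagation,
    snippet_split,
)
from mesocortex.simulation import paired_perturbation_simulate

from conftest import single_neuron_net


class TestRates:
    def test_count_over_window(self):
        raw, filt = compute_rates({0: np.linspace(0, 1900, 10)}, window=2000.0)
        assert raw[0] == pytest.approx(5.0)
        assert 0 in filt

    def test_low_rate_neurons_filtered_but_reported(self):
        trains = {0: np.array([100.0, 900.0]), 1: np.linspace(0, 4900, 50)}
        raw, filt = compute_rates(trains, window=5000.0)  # 0.4 and 10 spikes/s
        assert raw[0] == pytest.approx(0.4)
        assert 0 not in filt and 1 in filt

    def test_silent_neuron_rate_zero(self):
        raw, filt = compute_rates({0: np.empty(0)}, window=1000.0)
        assert raw[0] == 0.0
        assert 0 not in filt

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compute_rates({}, window=0.0)


class TestCvIsi:
    def test_regular_train_zero(self):
        assert cv_isi(np.arange(0.0, 1000.0, 10.0)) == 0.0

    def test_poisson_train_near_one(self):
        rng = np.random.default_rng(5)
        train = np.cumsum(rng.exponential(10.0, size=10_000))
        assert cv_isi(train) == pytest.approx(1.0, abs=0.03)

    def test_nine_spike_train_excluded(self):
        assert cv_isi(np.arange(9.0)) is None


class TestLvr:
    def test_regular_train_zero(self):
        assert lvr(np.arange(0.0, 1000.0, 10.0), refractoriness=0.0) == pytest.approx(0.0)

    def test_poisson_train_near_one(self):
        rng = np.random.default_rng(6)
        train = np.cumsum(rng.exponential(10.0, size=10_000))
        assert lvr(train, refractoriness=0.0) == pytest.approx(1.0, abs=0.05)

    def test_alternating_isis_closed_form(self):
        a, b = 4.0, 12.0
        isis = np.tile([a, b], 50)
        train = np.concatenate([[0.0], np.cumsum(isis)])
        expected = 3.0 * (1.0 - 4.0 * a * b / (a + b) ** 2)
        assert lvr(train, refractoriness=0.0) == pytest.approx(expected, rel=1e-12)

    def test_refractoriness_term_raises_value(self):
        rng = np.random.default_rng(7)
        train = np.cumsum(rng.exponential(10.0, size=5000))
        assert lvr(train, refractoriness=5.0) > lvr(train, refractoriness=0.0)


class TestPairwiseCorrelations:
    def test_identical_trains_fully_correlated(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 1000, 200))
        cc = pairwise_correlations({0: t, 1: t.copy()}, duration=1000.0)
        assert cc == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(9)
        trains = {
            i: np.cumsum(rng.exponential(20.0, size=600))[:500] for i in range(40)
        }
        cc = pairwise_correlations(trains, duration=10_000.0, bin_ms=1.0, seed=0)
        assert abs(cc.mean()) < 0.01

    def test_subsample_deterministic(self):
        rng = np.random.default_rng(10)
        trains = {i: np.sort(rng.uniform(0, 1000, 50)) for i in range(30)}
        c1 = pairwise_correlations(trains, 1000.0, subsample_size=10, seed=4)
        c2 = pairwise_correlations(trains, 1000.0, subsample_size=10, seed=4)
        np.testing.assert_array_equal(c1, c2)


class TestKsSimilarity:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ks_similarity(x, x.copy()) == 1.0

    def test_disjoint_supports(self):
        assert ks_similarity(np.arange(5.0), np.arange(10.0, 15.0)) == pytest.approx(0.0)

    def test_half_overlap_hand_value(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        assert ks_similarity(a, b) == pytest.approx(0.5)

    def test_symmetric_and_monotone_invariant(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=100), rng.normal(0.5, 1.2, size=80)
        s = ks_similarity(a, b)
        assert s == pytest.approx(ks_similarity(b, a))
        assert s == pytest.approx(ks_similarity(np.exp(a), np.exp(b)))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_similarity(np.empty(0), np.arange(3.0))


class TestSnippets:
    def test_single_snippet_identity(self):
        trains = {0: np.array([10.0, 500.0, 900.0])}
        out = snippet_split(trains, total=1000.0, n=1)
        np.testing.assert_array_equal(out[0][0], trains[0])

    def test_five_two_second_snippets(self):
        trains = {0: np.arange(0.0, 10_000.0, 100.0)}
        out = snippet_split(trains, total=10_000.0, n=5)
        assert len(out) == 5
        for snip in out:
            assert snip[0].size == 20
            assert snip[0].min() >= 0 and snip[0].max() < 2000.0

    def test_spikes_conserved_across_snippets(self):
        rng = np.random.default_rng(12)
        trains = {i: np.sort(rng.uniform(0, 10_000, 137)) for i in range(3)}
        out = snippet_split(trains, total=10_000.0, n=5)
        for i in trains:
            assert sum(s[i].size for s in out) == 137


class TestBoldProxyFc:
    def test_duplicated_trace_perfect_correlation(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=1000)
        fc = bold_proxy_fc(np.stack([x, x + 0.0, rng.normal(size=1000)]))
        assert fc[0, 1] == pytest.approx(1.0)
        assert np.allclose(fc, fc.T)
        assert np.allclose(np.diag(fc), 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(14)
        fc = bold_proxy_fc(rng.normal(size=(5, 10_000)))
        off = fc[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(15)
        c, n = 0.6, 20_000
        z = rng.normal(size=n)
        x = np.sqrt(c) * z + np.sqrt(1 - c) * rng.normal(size=n)
        y = np.sqrt(c) * z + np.sqrt(1 - c) * rng.normal(size=n)
        fc = bold_proxy_fc(np.stack([x, y]))
        se = (1 - c**2) / np.sqrt(n)
        assert abs(fc[0, 1] - c) < 3 * se

    def test_constant_trace_error_names_area(self):
        with pytest.raises(ValueError, match="flatarea"):
            bold_proxy_fc(
                np.stack([np.ones(100), np.random.default_rng(0).normal(size=100)]),
                area_names=["flatarea", "ok"],
            )


class TestFcSimilarity:
    def test_identical_matrices(self):
        rng = np.random.default_rng(16)
        fc = np.corrcoef(rng.normal(size=(6, 300)))
        assert fc_similarity(fc, fc) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_constant_offset_closed_form(self):
        rng = np.random.default_rng(17)
        fc = np.corrcoef(rng.normal(size=(6, 300))) * 0.5
        c = 0.1
        off = ~np.eye(6, dtype=bool)
        sigma = fc[off].std()
        pearson, rmse_based = fc_similarity(fc + c, fc)
        assert pearson == pytest.approx(1.0)
        assert rmse_based == pytest.approx(np.exp(-c / sigma))

    def test_anticorrelated_matrices(self):
        rng = np.random.default_rng(18)
        fc = np.corrcoef(rng.normal(size=(6, 300)))
        pearson, _ = fc_similarity(-fc, fc)
        assert pearson == pytest.approx(-1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fc_similarity(np.eye(3), np.eye(4))


class TestPropagation:
    def test_unperturbed_pair_no_propagation(self, small_net):
        from mesocortex.simulation import simulate

        a = simulate(small_net, 300.0, seed=2)
        b = simulate(small_net, 300.0, seed=2)
        trace = perturbation_propagation(a, b)
        assert trace.no_propagation

    def test_perturbed_population_flips_at_perturbation_bin(self):
        net = single_neuron_net(nu=0.0, k_ext=0.0, j_ext=0.0, n=10)
        control, perturbed = paired_perturbation_simulate(
            net, 200.0, seed=1, perturbation=(4, 50.0)
        )
        trace = perturbation_propagation(control, perturbed, perturbation_time=50.0)
        assert not trace.no_propagation
        assert trace.area_first_diff_ms["area0"] == pytest.approx(50.1, abs=1e-6)
        assert trace.mean_ms == pytest.approx(0.1, abs=1e-6)

    def test_binary_series_monotone(self):
        net = single_neuron_net(nu=0.0, k_ext=0.0, j_ext=0.0, n=10)
        control, perturbed = paired_perturbation_simulate(
            net, 200.0, seed=1, perturbation=(4, 50.0)
        )
        trace = perturbation_propagation(control, perturbed, perturbation_time=50.0)
        series = trace.binary_series(200.0)["area0:2/3E"]
        assert np.all(np.diff(series) >= 0)
        assert series[-1] == 1
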