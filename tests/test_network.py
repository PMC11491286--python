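"""Synapse parameterization: PSC conversion, weight/delay draws, realization."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mesocortex.network import realize_network
from mesocortex.params import (
    DelayParams,
    ExternalDriveParams,
    NeuronParams,
    SynapseModelParams,
    draw_delays,
    draw_weights,
    exponential_psc_eta_factor,
    external_poisson_rate,
    psp_to_psc,
)


class TestPspToPsc:
    def test_printed_amplitudes(self):
        assert round(psp_to_psc(0.1, 220.0, 10.0, 2.0), 1) == 16.4
        assert round(psp_to_psc(0.1, 100.0, 10.0, 2.0), 1) == 7.5

    def test_singular_time_constants_rejected(self):
        with pytest.raises(ValueError):
            psp_to_psc(0.1, 220.0, 10.0, 10.0)

    @pytest.mark.parametrize("c_m,tau_m,tau_s", [(220.0, 10.0, 2.0), (100.0, 10.0, 2.0), (150.0, 8.0, 3.0)])
    def test_ode_oracle_psp_peak(self, c_m, tau_m, tau_s):
        """Injecting the converted current into the subthreshold ODE produces
        a PSP peaking at exactly the requested amplitude."""
        psp = 0.1
        j = psp_to_psc(psp, c_m, tau_m, tau_s)

        def rhs(t, y):
            v, i = y
            return [-v / tau_m + i / c_m, -i / tau_s]

        sol = solve_ivp(rhs, [0.0, 10 * tau_m], [0.0, j], max_step=tau_s / 100)
        assert sol.y[0].max() == pytest.approx(psp, rel=5e-3)


class TestExternalRate:
    def test_formula_evaluation(self):
        nu = external_poisson_rate(ExternalDriveParams(), NeuronParams(), 1000.0)
        assert nu == pytest.approx(27.5)

    def test_zero_eta_gives_zero(self):
        assert external_poisson_rate(
            ExternalDriveParams(eta_ext=0.0), NeuronParams(), 500.0
        ) == 0.0

    @pytest.mark.parametrize("k", [100.0, 1000.0, 5000.0])
    def test_total_drive_invariant_in_k(self, k):
        drive, neuron = ExternalDriveParams(), NeuronParams()
        nu = external_poisson_rate(drive, neuron, k)
        total = nu * k * drive.w_ext * neuron.tau_m * 1e-3
        assert total == pytest.approx(drive.eta_ext * (neuron.v_th - neuron.e_l))

    def test_strict_mode_rescales_by_exponential_factor(self):
        neuron = NeuronParams()
        nu_v = external_poisson_rate(ExternalDriveParams(), neuron, 1000.0)
        nu_s = external_poisson_rate(
            ExternalDriveParams(strict_eta=True), neuron, 1000.0
        )
        assert nu_v / nu_s == pytest.approx(
            exponential_psc_eta_factor(neuron.tau_m, neuron.tau_s)
        )


class TestDrawWeights:
    def test_zero_sd_all_equal(self):
        rng = np.random.default_rng(0)
        w = draw_weights(100, 16.4, 0.0, 1, rng)
        assert np.all(w == 16.4)

    def test_truncation_no_wrong_sign(self):
        rng = np.random.default_rng(1)
        w = draw_weights(1_000_000, 16.4, 0.1, 1, rng)
        assert np.all(w > 0)
        wi = draw_weights(100_000, -82.0, 0.1, -1, rng)
        assert np.all(wi < 0)

    def test_sample_mean_within_three_se(self):
        rng = np.random.default_rng(2)
        n, mean, rel_sd = 1_000_000, 16.4, 0.1
        w = draw_weights(n, mean, rel_sd, 1, rng)
        se = rel_sd * mean / np.sqrt(n)
        assert abs(w.mean() - mean) < 3 * se


class TestDrawDelays:
    def test_zero_sd_rounds_mean(self):
        rng = np.random.default_rng(0)
        d = draw_delays(100, 1.5, 0.0, 0.1, rng)
        assert np.all(d == 15)

    def test_no_delay_below_one_step(self):
        rng = np.random.default_rng(1)
        d = draw_delays(1_000_000, 0.75, 0.5, 0.1, rng)
        assert d.min() >= 1

    def test_sample_mean_within_two_percent(self):
        rng = np.random.default_rng(2)
        d = draw_delays(1_000_000, 15.0, 0.5, 0.1, rng)
        assert d.mean() * 0.1 == pytest.approx(15.0, rel=0.02)


class TestRealizeNetwork:
    def test_per_projection_counts_exact(self, small_bundle, small_connectome, small_net):
        """The fixed-total-number rule: realized synapse counts equal the
        scaled specification exactly for every projection."""
        grid, counts = small_connectome
        net = small_net
        table = net.synapse_table()
        pop_of = net.pop_of_neuron
        realized = np.zeros_like(counts.internal)
        np.add.at(
            realized,
            (pop_of[table["target"].to_numpy()], pop_of[table["source"].to_numpy()]),
            1,
        )
        expected = np.round(counts.internal * net.scale).astype(np.int64)
        # projections whose endpoints scaled to zero neurons are dropped
        sizes = net.pop_sizes
        alive = (sizes > 0)[:, None] & (sizes > 0)[None, :]
        np.testing.assert_array_equal(realized[alive], expected[alive])
        assert realized[~alive].sum() == 0

    def test_weight_signs_follow_source_type(self, small_net):
        table = small_net.synapse_table()
        src_e = small_net.is_excitatory()[table["source"].to_numpy()]
        w = table["weight_pa"].to_numpy()
        assert np.all(w[src_e] > 0)
        assert np.all(w[~src_e] < 0)

    def test_chi_one_matches_intra_and_inter_weights(self, small_bundle, small_connectome):
        grid, counts = small_connectome
        net = realize_network(
            counts, grid, small_bundle.tracts,
            synapse=SynapseModelParams(chi=1.0, chi_i=1.0),
            scale=0.001, seed=3,
        )
        table = net.synapse_table()
        pop_area = np.array(
            [net.area_names.index(p.area) for p in net.populations]
        )
        src_pop = net.pop_of_neuron[table["source"].to_numpy()]
        tgt_pop = net.pop_of_neuron[table["target"].to_numpy()]
        is_e = np.array([p.ei == "E" for p in net.populations])
        src_layer = np.array([p.layer for p in net.populations])[src_pop]
        tgt_layer = np.array([p.layer for p in net.populations])[tgt_pop]
        same = pop_area[src_pop] == pop_area[tgt_pop]
        ee = is_e[src_pop] & is_e[tgt_pop]
        not_l4_boost = ~((src_layer == "4") & (tgt_layer == "2/3"))
        w = table["weight_pa"].to_numpy()
        intra = w[same & ee & not_l4_boost]
        inter = w[~same & ee]
        assert intra.mean() == pytest.approx(inter.mean(), rel=0.01)

    def test_l4e_to_l23e_doubling_within_area(self, small_net):
        table = small_net.synapse_table()
        pops = small_net.populations
        pop_area = np.array([small_net.area_names.index(p.area) for p in pops])
        src_pop = small_net.pop_of_neuron[table["source"].to_numpy()]
        tgt_pop = small_net.pop_of_neuron[table["target"].to_numpy()]
        is_e = np.array([p.ei == "E" for p in pops])
        layer = np.array([p.layer for p in pops])
        same = pop_area[src_pop] == pop_area[tgt_pop]
        boosted = (
            same
            & (layer[src_pop] == "4")
            & (layer[tgt_pop] == "2/3")
            & is_e[src_pop]
            & is_e[tgt_pop]
        )
        plain = (
            same
            & (layer[src_pop] == "2/3")
            & (layer[tgt_pop] == "2/3")
            & is_e[src_pop]
            & is_e[tgt_pop]
        )
        w = table["weight_pa"].to_numpy()
        assert w[boosted].mean() == pytest.approx(2 * w[plain].mean(), rel=0.02)

    def test_inter_areal_delay_hand_arithmetic(self, small_bundle, small_connectome):
        """Fiber length 35 mm at 3.5 m/s gives a 10 ms mean delay."""
        grid, counts = small_connectome
        bundle = small_bundle
        bundle.tracts.fiber_length[:] = np.where(
            np.eye(bundle.n_areas), 0.0, 35.0
        )
        net = realize_network(counts, grid, bundle.tracts, scale=0.001, seed=5)
        table = net.synapse_table()
        pop_area = np.array([net.area_names.index(p.area) for p in net.populations])
        src_pop = net.pop_of_neuron[table["source"].to_numpy()]
        tgt_pop = net.pop_of_neuron[table["target"].to_numpy()]
        inter = pop_area[src_pop] != pop_area[tgt_pop]
        mean_ms = table["delay_steps"].to_numpy()[inter].mean() * net.delay.dt
        assert mean_ms == pytest.approx(10.0, rel=0.02)

    def test_deterministic_given_seed(self, small_bundle, small_connectome):
        grid, counts = small_connectome
        nets = [
            realize_network(counts, grid, small_bundle.tracts, scale=0.001, seed=9)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(nets[0].syn_target, nets[1].syn_target)
        np.testing.assert_array_equal(nets[0].syn_weight, nets[1].syn_weight)
        np.testing.assert_array_equal(nets[0].syn_delay, nets[1].syn_delay)

    def test_invalid_scale_rejected(self, small_bundle, small_connectome):
        grid, counts = small_connectome
        with pytest.raises(ValueError):
            realize_network(counts, grid, small_bundle.tracts, scale=0.0)
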