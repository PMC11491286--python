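"""Connectome construction: budgets, allocation heuristics, laminar patterns."""

import numpy as np
import pytest
from scipy.special import ndtr

from mesocortex.anatomy import (
    AnatomyBundle,
    DendriticProfile,
    LocalBlueprint,
    ModelConstants,
    SLNFitParams,
    AreaAnatomy,
    TractData,
    DEFAULT_EI_TARGET_EXC_PROB,
)
from mesocortex.areas import LAYERS, POPULATION_LABELS, SYNAPSE_LAYERS
from mesocortex.connectome import (
    ConnectomeError,
    allocate_integers,
    allocate_longrange_sources,
    assemble_connectome,
    compute_area_synapse_budget,
    compute_population_sizes,
    distribute_external_drive,
    distribute_internal,
    laminar_source_counts,
    laminar_target_distribution,
    nonlocal_fraction,
    predict_sln,
    resolve_postsynaptic_targets,
    split_synapse_budget,
)
from mesocortex.synth import synth_anatomy


def make_area(name="a", dens=50e3, h=None, surface=500.0, exc=None, l1=0.2):
    h = h or {"2/3": 0.8, "4": 0.3, "5": 0.5, "6": 0.5}
    return AreaAnatomy(
        name=name,
        surface_area=surface,
        layer_thickness=dict(h),
        neuron_density={layer: dens for layer in LAYERS},
        excitatory_fraction=exc or None or {},
        l1_thickness=l1,
    )


class TestAllocateIntegers:
    def test_exact_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.random(rng.integers(2, 50))
            total = int(rng.integers(0, 10**9))
            out = allocate_integers(total, w)
            assert out.sum() == total
            ideal = w / w.sum() * total
            assert np.all(np.abs(out - ideal) < 1.0)

    def test_zero_weights_rejected(self):
        with pytest.raises(ConnectomeError):
            allocate_integers(10, np.zeros(3))


class TestPopulationSizes:
    def test_hand_arithmetic(self):
        area = AreaAnatomy(
            name="x",
            surface_area=100.0,
            layer_thickness={"2/3": 0.5, "4": 0.0, "5": 0.0, "6": 0.0},
            neuron_density={"2/3": 50_000.0, "4": 0.0, "5": 0.0, "6": 0.0},
            excitatory_fraction={"2/3": 0.8, "4": 0.79, "5": 0.78, "6": 0.86},
        )
        bundle = AnatomyBundle(
            areas=[area, make_area("y")],
            tracts=TractData(nos=np.ones((2, 2)), fiber_length=np.full((2, 2), 10.0)),
            blueprint=LocalBlueprint.default(),
            dendrites=DendriticProfile.default(),
        )
        grid = compute_population_sizes(bundle)
        assert grid.sizes[grid.index("x", "2/3", "E")] == 20_000
        assert grid.sizes[grid.index("x", "2/3", "I")] == 5_000
        # absent layers have zero neurons but keep their slots
        assert grid.sizes[grid.index("x", "4", "E")] == 0
        assert grid.sizes[grid.index("x", "4", "I")] == 0
        assert grid.n_populations == 16

    def test_all_excitatory_boundary(self):
        area = make_area(exc={layer: 1.0 for layer in LAYERS})
        bundle = AnatomyBundle(
            areas=[area, make_area("y")],
            tracts=TractData(nos=np.ones((2, 2)), fiber_length=np.full((2, 2), 10.0)),
            blueprint=LocalBlueprint.default(),
            dendrites=DendriticProfile.default(),
        )
        grid = compute_population_sizes(bundle)
        for layer in LAYERS:
            assert grid.sizes[grid.index("a", layer, "I")] == 0


class TestSynapseBudget:
    def test_hand_arithmetic(self):
        area = make_area(h={"2/3": 1.0, "4": 0.5, "5": 0.5, "6": 0.5}, l1=0.0)
        bundle = AnatomyBundle(
            areas=[area, make_area("y")],
            tracts=TractData(nos=np.ones((2, 2)), fiber_length=np.full((2, 2), 10.0)),
            blueprint=LocalBlueprint.default(),
            dendrites=DendriticProfile.default(),
        )
        assert compute_area_synapse_budget(bundle, "a") == int(round(6.6e8 * 2.5))

    def test_budget_linear_in_density(self):
        area = make_area()
        c1 = ModelConstants()
        c2 = ModelConstants(rho_synapse=c1.rho_synapse / 2)
        b1 = AnatomyBundle(
            areas=[area, make_area("y")],
            tracts=TractData(nos=np.ones((2, 2)), fiber_length=np.full((2, 2), 10.0)),
            blueprint=LocalBlueprint.default(),
            dendrites=DendriticProfile.default(),
            constants=c1,
        )
        b2 = AnatomyBundle(
            areas=[area, make_area("y")],
            tracts=b1.tracts,
            blueprint=b1.blueprint,
            dendrites=b1.dendrites,
            constants=c2,
        )
        assert compute_area_synapse_budget(b1, "a") == 2 * compute_area_synapse_budget(b2, "a")


class TestNonlocalFraction:
    def test_printed_human_value(self):
        assert round(nonlocal_fraction(ModelConstants()), 2) == 0.14

    def test_calibration_point(self):
        c = ModelConstants(human_neurons=1.4e9)
        assert nonlocal_fraction(c) == pytest.approx(0.21)

    def test_degenerate_exponent(self):
        c = ModelConstants(scaling_exponent=1e-12)
        assert nonlocal_fraction(c) == pytest.approx(0.21, abs=1e-6)


class TestSplitBudget:
    def test_all_internal_limit(self):
        n_int, n_ext, n_nl = split_synapse_budget(1000, 0.0, 1.0, 0.0)
        assert (n_int, n_ext, n_nl) == (1000, 0, 0)

    def test_symmetric_densities(self):
        n_int, n_ext, n_nl = split_synapse_budget(10**9, 0.14, 1.0, 1.0)
        assert n_nl == round(0.14 * 10**9)
        assert abs(n_int - n_ext) <= 1
        assert n_int + n_ext + n_nl == 10**9

    def test_hand_arithmetic_nonlocal(self):
        _, _, n_nl = split_synapse_budget(1_650_000_000, 0.14, 1.0, 1.0)
        assert n_nl == 231_000_000


class TestDistributeInternal:
    def test_uniform_symmetry(self):
        bp = LocalBlueprint(q_pd=np.ones((8, 8)), k_ext_pd=np.ones(8))
        sizes = np.full(8, 100)
        out = distribute_internal(bp, sizes, 64_000)
        assert out.sum() == 64_000
        assert out.max() - out.min() <= 1

    def test_single_pair_gets_everything(self):
        q = np.zeros((8, 8))
        q[2, 5] = 1.0
        bp = LocalBlueprint(q_pd=q, k_ext_pd=np.ones(8))
        out = distribute_internal(bp, np.full(8, 10), 999)
        assert out[2, 5] == 999
        assert out.sum() == 999

    def test_zero_population_isolated(self):
        bp = LocalBlueprint(q_pd=np.ones((8, 8)), k_ext_pd=np.ones(8))
        sizes = np.full(8, 100)
        sizes[3] = 0
        out = distribute_internal(bp, sizes, 10_000)
        assert out[3, :].sum() == 0
        assert out[:, 3].sum() == 0
        assert out.sum() == 10_000


class TestDistributeExternal:
    def test_equal_split(self):
        bp = LocalBlueprint(q_pd=np.ones((8, 8)), k_ext_pd=np.full(8, 1000.0))
        out = distribute_external_drive(bp, np.full(8, 50), 8_000)
        assert np.all(out == 1000)

    def test_hand_arithmetic(self):
        k = np.zeros(8)
        k[0], k[1] = 2000.0, 1000.0
        sizes = np.zeros(8)
        sizes[0], sizes[1] = 100, 200
        bp = LocalBlueprint(q_pd=np.ones((8, 8)), k_ext_pd=k)
        out = distribute_external_drive(bp, sizes, 400_000)
        assert out[0] == 200_000 and out[1] == 200_000

    def test_empty_population_receives_nothing(self):
        bp = LocalBlueprint(q_pd=np.ones((8, 8)), k_ext_pd=np.full(8, 1000.0))
        sizes = np.full(8, 50)
        sizes[4] = 0
        out = distribute_external_drive(bp, sizes, 7000)
        assert out[4] == 0 and out.sum() == 7000


class TestLongrangeSources:
    def _tracts(self, nos):
        n = nos.shape[0]
        return TractData(nos=nos, fiber_length=np.where(np.eye(n), 0.0, 10.0))

    def test_equal_sources(self):
        nos = np.ones((4, 4))
        out = allocate_longrange_sources(self._tracts(nos), 0, 300)
        assert out[0] == 0
        assert np.all(out[1:] == 100)

    def test_zero_streamlines_zero_synapses(self):
        nos = np.ones((3, 3))
        nos[2, 0] = 0.0
        out = allocate_longrange_sources(self._tracts(nos), 0, 100)
        assert out[2] == 0 and out.sum() == 100

    def test_isolated_area_error_names_area(self):
        nos = np.zeros((3, 3))
        with pytest.raises(ConnectomeError, match="isolated|streamlines"):
            allocate_longrange_sources(self._tracts(nos), 1, 10, ["x", "lonely", "z"])


class TestPredictSln:
    def test_equal_densities(self):
        assert predict_sln(1.0, 1.0, SLNFitParams()) == pytest.approx(
            float(ndtr(-0.152)), abs=1e-9
        )
        assert round(predict_sln(40e3, 40e3, SLNFitParams()), 4) == 0.4396

    def test_dense_target_limit(self):
        assert predict_sln(1e6, 1.0, SLNFitParams()) < 1e-6

    def test_strictly_decreasing_in_ratio(self):
        fit = SLNFitParams()
        ratios = np.logspace(-2, 2, 25)
        vals = [predict_sln(r, 1.0, fit) for r in ratios]
        assert np.all(np.diff(vals) < 0)
        assert all(0 < v < 1 for v in vals)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ConnectomeError):
            predict_sln(0.0, 1.0, SLNFitParams())


class TestLaminarSource:
    def sizes(self, n23e=100, n5e=300, n6e=100):
        s = np.zeros(8)
        s[POPULATION_LABELS.index("2/3E")] = n23e
        s[POPULATION_LABELS.index("5E")] = n5e
        s[POPULATION_LABELS.index("6E")] = n6e
        return s

    def test_pure_supragranular(self):
        out = laminar_source_counts(1.0, self.sizes(), 500)
        assert out[POPULATION_LABELS.index("2/3E")] == 500
        assert out.sum() == 500

    def test_infragranular_even_split(self):
        out = laminar_source_counts(0.0, self.sizes(n5e=200, n6e=200), 400)
        assert out[POPULATION_LABELS.index("5E")] == 200
        assert out[POPULATION_LABELS.index("6E")] == 200

    def test_hand_arithmetic(self):
        out = laminar_source_counts(0.6, self.sizes(100, 300, 100), 1000)
        assert out[POPULATION_LABELS.index("2/3E")] == 600
        assert out[POPULATION_LABELS.index("5E")] == 300
        assert out[POPULATION_LABELS.index("6E")] == 100

    def test_inhibitory_and_l4_never_project(self):
        out = laminar_source_counts(0.5, self.sizes(), 1000)
        for label in ("2/3I", "4E", "4I", "5I", "6I"):
            assert out[POPULATION_LABELS.index(label)] == 0

    def test_no_eligible_source_rejected(self):
        with pytest.raises(ConnectomeError):
            laminar_source_counts(0.5, np.zeros(8), 10)


class TestLaminarTarget:
    def test_feedforward_granular(self):
        w = laminar_target_distribution(0.9, {"1": 0.2, "2/3": 1.0, "4": 0.3, "5": 0.5, "6": 0.5}, False)
        assert w[SYNAPSE_LAYERS.index("4")] == 1.0
        assert w.sum() == 1.0

    def test_feedforward_agranular_redirects_to_23(self):
        w = laminar_target_distribution(0.9, {"1": 0.2, "2/3": 1.0, "4": 0.0, "5": 0.5, "6": 0.5}, True)
        assert w[SYNAPSE_LAYERS.index("2/3")] == 1.0

    def test_feedback_thickness_weighting(self):
        w = laminar_target_distribution(
            0.2, {"1": 0.2, "2/3": 0.8, "4": 0.3, "5": 0.6, "6": 0.4}, False
        )
        np.testing.assert_allclose(w, [0.1, 0.4, 0.0, 0.3, 0.2])

    def test_lateral_uses_all_layers(self):
        th = {"1": 0.5, "2/3": 0.5, "4": 0.5, "5": 0.5, "6": 0.5}
        w = laminar_target_distribution(0.5, th, False)
        np.testing.assert_allclose(w, 0.2)

    def test_zero_pattern_thickness_rejected(self):
        with pytest.raises(ConnectomeError):
            laminar_target_distribution(0.2, {"1": 0.0, "2/3": 0.0, "5": 0.0, "6": 0.0}, False)


class TestResolveTargets:
    def test_diagonal_dendrites_keep_layer(self):
        """With somata only below their own-layer dendrites, excitatory
        synapses stay in the synapse layer."""
        ell = np.zeros((5, 4))
        for i, layer in enumerate(LAYERS):
            ell[SYNAPSE_LAYERS.index(layer), i] = 1.0
        ell[0, 0] = 1.0  # layer-1 dendrites belong to 2/3 somata
        dend = DendriticProfile(ell=ell)
        w = np.zeros(5)
        w[SYNAPSE_LAYERS.index("5")] = 1.0
        probs = {layer: 1.0 for layer in SYNAPSE_LAYERS}  # all excitatory
        out = resolve_postsynaptic_targets(w, probs, dend, 0.5, ModelConstants())
        assert out[POPULATION_LABELS.index("5E")] == pytest.approx(1.0)

    def test_feedback_excitatory_share_fixed(self):
        out = resolve_postsynaptic_targets(
            np.array([0.1, 0.4, 0.0, 0.3, 0.2]),
            DEFAULT_EI_TARGET_EXC_PROB,
            DendriticProfile.default(),
            sln=0.2,
            constants=ModelConstants(),
        )
        exc_share = out[0::2].sum()
        assert exc_share == pytest.approx(0.93, abs=1e-12)

    def test_uniform_layer1_row_splits_evenly(self):
        ell = DendriticProfile.default().ell.copy()
        ell[0] = 1.0  # uniform layer-1 dendrite row
        w = np.zeros(5)
        w[0] = 1.0  # all synapses in layer 1
        probs = dict(DEFAULT_EI_TARGET_EXC_PROB)
        probs["1"] = 1.0  # fully excitatory
        out = resolve_postsynaptic_targets(
            w, probs, DendriticProfile(ell=ell), 0.5, ModelConstants()
        )
        np.testing.assert_allclose(out[0::2], 0.25)
        np.testing.assert_allclose(out[1::2], 0.0)


class TestAssemble:
    def test_two_area_conservation(self):
        bundle, _ = synth_anatomy(seed=21, n_areas=2)
        grid, counts = assemble_connectome(bundle)
        for area in bundle.area_names:
            bk = counts.bookkeeping[area]
            assert bk["N_internal"] + bk["N_external"] == bk["N_local"]
            assert bk["N_local"] + bk["N_nonlocal"] == bk["N_total"]
            sl = grid.area_slice(area)
            assert counts.internal[sl, sl].sum() == bk["N_internal"]
            assert counts.external_drive[sl].sum() == bk["N_external"]
            # off-diagonal blocks into this area hold the nonlocal budget
            other = [a for a in bundle.area_names if a != area]
            inter = sum(
                counts.internal[sl, grid.area_slice(o)].sum() for o in other
            )
            assert inter == bk["N_nonlocal"]

    def test_isolated_areas_rejected(self):
        bundle, _ = synth_anatomy(seed=22, n_areas=3)
        bundle.tracts.nos[:] = 0.0
        with pytest.raises(ConnectomeError):
            assemble_connectome(bundle)

    def test_agranular_area_has_silent_layer4(self):
        bundle, _ = synth_anatomy(seed=23, n_areas=3)
        a0 = bundle.areas[0]
        a0.layer_thickness["4"] = 0.0
        grid, counts = assemble_connectome(bundle)
        for ei in ("E", "I"):
            idx = grid.index(a0.name, "4", ei)
            assert grid.sizes[idx] == 0
            assert counts.internal[idx, :].sum() == 0
            assert counts.internal[:, idx].sum() == 0
            assert counts.external_drive[idx] == 0
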