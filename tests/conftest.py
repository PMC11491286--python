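"""Shared fixtures: small synthetic bundles, connectomes and networks."""

import numpy as np
import pytest

from mesocortex.connectome import assemble_connectome
from mesocortex.network import realize_network
from mesocortex.params import DelayParams, ExternalDriveParams, NeuronParams, SynapseModelParams
from mesocortex.synth import synth_anatomy


@pytest.fixture(scope="session")
def small_bundle():
    bundle, spec = synth_anatomy(seed=11, n_areas=4)
    return bundle


@pytest.fixture(scope="session")
def small_connectome(small_bundle):
    return assemble_connectome(small_bundle)


@pytest.fixture(scope="session")
def small_net(small_bundle, small_connectome):
    grid, counts = small_connectome
    return realize_network(
        counts,
        grid,
        small_bundle.tracts,
        neuron=NeuronParams(),
        synapse=SynapseModelParams(),
        delay=DelayParams(),
        drive=ExternalDriveParams(),
        scale=0.001,
        seed=42,
    )


def single_neuron_net(nu: float, k_ext: float, j_ext: float, n: int = 1):
    """An unconnected network of ``n`` excitatory neurons with Poisson drive."""
    from mesocortex.connectome import Population
    from mesocortex.network import NetworkRealization

    return NetworkRealization(
        populations=[Population("area0", "2/3", "E")],
        pop_sizes=np.array([n], dtype=np.int64),
        pop_offset=np.array([0, n], dtype=np.int64),
        pop_of_neuron=np.zeros(n, dtype=np.int32),
        indptr=np.zeros(n + 1, dtype=np.int64),
        syn_target=np.empty(0, dtype=np.int32),
        syn_weight=np.empty(0, dtype=np.float32),
        syn_delay=np.empty(0, dtype=np.int16),
        nu_ext_pop=np.array([nu]),
        k_ext_pop=np.array([k_ext]),
        j_ext_pop=np.array([j_ext]),
        neuron=NeuronParams(),
        synapse=SynapseModelParams(),
        delay=DelayParams(),
        drive=ExternalDriveParams(),
        area_names=["area0"],
        scale=1.0,
        seed=0,
    )
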