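"""Explicit network realization from a synapse-count matrix.

Connectivity follows the "random, fixed total number" rule: for every
projection (source population -> target population) exactly the specified
number of synapses is created, with source and target neurons drawn randomly
with replacement (autapses and multapses allowed). Weights are drawn from
sign-truncated normal distributions around the converted postsynaptic-
current amplitude of a 0.1 mV PSP, with the model's scaling factors (g for
inhibitory sources, the within-area 4E->2/3E doubling, chi for inter-areal
synapses, chi_I additionally onto inhibitory targets). Delays are truncated
log-normal around population-level means (local: 1.5/0.75 ms; inter-areal:
fiber length / conduction velocity), rounded to the simulation grid.

Synapses are stored grouped by source neuron (CSR layout) in compact dtypes
so that down-scaled instantiations of the full 34-area model fit in memory.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .areas import POPULATION_LABELS
from .connectome import Population, PopulationGrid, SynapseCounts
from .params import (
    DelayParams,
    ExternalDriveParams,
    NeuronParams,
    SynapseModelParams,
    draw_delays,
    draw_weights,
    external_poisson_rate,
    psp_to_psc,
)

logger = logging.getLogger(__name__)

__all__ = ["NetworkRealization", "realize_network"]


@dataclasses.dataclass
class NetworkRealization:
    """A concrete (possibly down-scaled) network instantiation.

    Synapses are stored in CSR layout by source neuron: neuron ``i``'s
    outgoing synapses are ``syn_target[indptr[i]:indptr[i+1]]`` with matching
    weights (pA) and delays (simulation steps). Per-neuron randomness during
    simulation uses one counter-based stream per neuron keyed by
    ``(simulation seed, neuron id)``; the realization itself is built from a
    single stream seeded with ``seed``.
    """

    populations: list[Population]
    pop_sizes: np.ndarray  # scaled neuron counts, int64
    pop_offset: np.ndarray  # first neuron id per population
    pop_of_neuron: np.ndarray  # int32
    indptr: np.ndarray  # int64, len n_neurons + 1
    syn_target: np.ndarray  # int32
    syn_weight: np.ndarray  # float32, pA
    syn_delay: np.ndarray  # int32, steps
    nu_ext_pop: np.ndarray  # spikes/s per external synapse, per population
    k_ext_pop: np.ndarray  # external indegree per population (unscaled)
    j_ext_pop: np.ndarray  # pA, mean external PSC per population
    neuron: NeuronParams
    synapse: SynapseModelParams
    delay: DelayParams
    drive: ExternalDriveParams
    area_names: list[str]
    scale: float
    seed: int
    rng_layout: str = "philox(key = (seed << 64) + neuron_id) per neuron"
    # optional per-neuron distributed parameters (None = homogeneous)
    v_th_of_neuron: np.ndarray | None = None
    c_m_of_neuron: np.ndarray | None = None
    tau_m_of_neuron: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.pop_of_neuron.size

    @property
    def n_synapses(self) -> int:
        return self.syn_target.size

    def is_excitatory(self) -> np.ndarray:
        pop_exc = np.array([p.ei == "E" for p in self.populations])
        return pop_exc[self.pop_of_neuron]

    def area_of_neuron(self) -> np.ndarray:
        pop_area = np.array(
            [self.area_names.index(p.area) for p in self.populations], dtype=np.int32
        )
        return pop_area[self.pop_of_neuron]

    def synapse_table(self, max_synapses: int = 5_000_000) -> pd.DataFrame:
        """Explicit synapse list (source, target, weight, delay_steps)."""
        if self.n_synapses > max_synapses:
            raise ValueError(
                f"{self.n_synapses} synapses exceed max_synapses={max_synapses}"
            )
        source = np.repeat(
            np.arange(self.n_neurons, dtype=np.int64), np.diff(self.indptr)
        )
        return pd.DataFrame(
            {
                "source": source,
                "target": self.syn_target.astype(np.int64),
                "weight_pa": self.syn_weight.astype(float),
                "delay_steps": self.syn_delay.astype(np.int64),
            }
        )


def realize_network(
    counts: SynapseCounts,
    grid: PopulationGrid,
    tracts,
    neuron: NeuronParams | None = None,
    synapse: SynapseModelParams | None = None,
    delay: DelayParams | None = None,
    drive: ExternalDriveParams | None = None,
    scale: float = 1.0,
    seed: int = 0,
    weight_rescale: bool = False,
) -> NetworkRealization:
    """Instantiate an explicit network from population-level synapse counts.

    ``scale`` multiplies both neuron and synapse counts (preserving
    indegrees). With ``weight_rescale`` the weights are additionally
    multiplied by 1/sqrt(scale), which preserves input fluctuations at the
    cost of deviating from the full-density parameterization. Projections
    whose scaled endpoint populations are empty are dropped with a warning.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    neuron = neuron or NeuronParams()
    synapse = synapse or SynapseModelParams()
    delay = delay or DelayParams()
    drive = drive or ExternalDriveParams()
    rng = np.random.default_rng(seed)

    n_per = len(POPULATION_LABELS)
    pops = grid.populations
    n_pop = len(pops)
    sizes = np.round(grid.sizes * scale).astype(np.int64)
    offset = np.concatenate([[0], np.cumsum(sizes)])
    n_neurons = int(offset[-1])
    pop_of_neuron = np.repeat(np.arange(n_pop, dtype=np.int32), sizes)

    area_index = {name: i for i, name in enumerate(grid.area_names)}
    pop_area = np.array([area_index[p.area] for p in pops])
    pop_is_e = np.array([p.ei == "E" for p in pops])
    pop_layer = [p.layer for p in pops]

    # mean PSC per (target pop, source pop) and mean delay per projection
    conv_e = psp_to_psc(1.0, neuron.c_m_exc, neuron.tau_m, neuron.tau_s)
    conv_i = psp_to_psc(1.0, neuron.c_m_inh, neuron.tau_m, neuron.tau_s)

    tgt_idx, src_idx = np.nonzero(counts.internal)
    n_syn_scaled = np.round(counts.internal[tgt_idx, src_idx] * scale).astype(np.int64)
    keep = n_syn_scaled > 0
    tgt_idx, src_idx, n_syn_scaled = tgt_idx[keep], src_idx[keep], n_syn_scaled[keep]

    dropped = 0
    proj: list[tuple[int, int, int]] = []
    for t, s, m in zip(tgt_idx, src_idx, n_syn_scaled):
        if sizes[t] == 0 or sizes[s] == 0:
            dropped += int(m)
            continue
        proj.append((int(t), int(s), int(m)))
    if dropped:
        logger.warning(
            "scale=%g maps %d synapses onto empty populations; dropped", scale, dropped
        )

    # phase 1: multinomial split of each projection over its source neurons
    out_counts = np.zeros(n_neurons, dtype=np.int64)
    per_proj_counts: list[np.ndarray] = []
    for t, s, m in proj:
        c = rng.multinomial(m, np.full(sizes[s], 1.0 / sizes[s]))
        per_proj_counts.append(c)
        out_counts[offset[s]:offset[s] + sizes[s]] += c
    indptr = np.concatenate([[0], np.cumsum(out_counts)])
    total_syn = int(indptr[-1])

    syn_target = np.empty(total_syn, dtype=np.int32)
    syn_weight = np.empty(total_syn, dtype=np.float32)
    # int16 steps: 3.3 s at dt = 0.1 ms, far beyond any drawn delay
    syn_delay = np.empty(total_syn, dtype=np.int16)
    cursor = indptr[:-1].copy()

    w_scale = 1.0 / np.sqrt(scale) if weight_rescale else 1.0
    for (t, s, m), c in zip(proj, per_proj_counts):
        same_area = pop_area[t] == pop_area[s]
        psp = synapse.psp_mean
        if pop_is_e[s]:
            sign = 1
            if same_area and pop_layer[s] == "4" and pop_layer[t] == "2/3" and pop_is_e[t]:
                psp *= synapse.l4e_to_l23e_factor
        else:
            sign = -1
            psp *= synapse.g
        if not same_area:
            psp *= synapse.chi
            if not pop_is_e[t]:
                psp *= synapse.chi_i
        conv = conv_e if pop_is_e[t] else conv_i
        mean_pa = sign * psp * conv * w_scale

        if same_area:
            d_mean = delay.d_e if pop_is_e[s] else delay.d_i
        else:
            d_mean = tracts.fiber_length[pop_area[s], pop_area[t]] / delay.v_t

        starts = cursor[offset[s]:offset[s] + sizes[s]]
        shifts = np.cumsum(c) - c
        pos = np.repeat(starts - shifts, c) + np.arange(m)
        syn_target[pos] = rng.integers(offset[t], offset[t] + sizes[t], size=m)
        syn_weight[pos] = draw_weights(m, mean_pa, synapse.psp_rel_sd, sign, rng)
        syn_delay[pos] = np.minimum(
            draw_delays(m, d_mean, delay.rel_sd, delay.dt, rng), 32000
        )
        cursor[offset[s]:offset[s] + sizes[s]] += c

    # external drive: indegrees from the unscaled counts (indegree-preserving)
    k_ext = np.zeros(n_pop)
    nz = grid.sizes > 0
    k_ext[nz] = counts.external_drive[nz] / grid.sizes[nz]
    nu_ext = np.zeros(n_pop)
    for i in range(n_pop):
        if k_ext[i] > 0:
            nu_ext[i] = external_poisson_rate(drive, neuron, k_ext[i])
        elif counts.external_drive[i] > 0:
            raise ValueError(
                f"population {pops[i].label} has external synapses but no neurons"
            )
    j_ext = np.zeros(n_pop)
    for i, p in enumerate(pops):
        w = drive.w_ext
        if p.layer == "5" and p.ei == "E":
            w *= synapse.ext_scale_5e
        if p.layer == "6" and p.ei == "E":
            w *= synapse.ext_scale_6e
        j_ext[i] = w * (conv_e if p.ei == "E" else conv_i) * w_scale

    net = NetworkRealization(
        populations=list(pops),
        pop_sizes=sizes,
        pop_offset=offset,
        pop_of_neuron=pop_of_neuron,
        indptr=indptr,
        syn_target=syn_target,
        syn_weight=syn_weight,
        syn_delay=syn_delay,
        nu_ext_pop=nu_ext,
        k_ext_pop=k_ext,
        j_ext_pop=j_ext,
        neuron=neuron,
        synapse=synapse,
        delay=delay,
        drive=drive,
        area_names=list(grid.area_names),
        scale=scale,
        seed=seed,
    )

    if neuron.cv_table:
        _draw_distributed_params(net, rng)
    return net


def _lognormal_with_mean_cv(mean: float, cv: float, n: int, rng) -> np.ndarray:
    if cv <= 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2), n)


def _draw_distributed_params(net: NetworkRealization, rng) -> None:
    """Optionally distribute V_th, C_m, tau_m log-normally (off by default).

    Weight conversion keeps using the population-mean parameters."""
    cv = net.neuron.cv_table
    is_e = net.is_excitatory()
    n = net.n_neurons
    v_th = np.full(n, net.neuron.v_th)
    c_m = np.where(is_e, net.neuron.c_m_exc, net.neuron.c_m_inh).astype(float)
    tau_m = np.full(n, net.neuron.tau_m)
    if "v_th" in cv:
        # distribute the distance to threshold, keep the leak potential fixed
        dist = _lognormal_with_mean_cv(net.neuron.v_th - net.neuron.e_l, cv["v_th"], n, rng)
        v_th = net.neuron.e_l + dist
    if "c_m_exc" in cv or "c_m_inh" in cv:
        e_vals = _lognormal_with_mean_cv(net.neuron.c_m_exc, cv.get("c_m_exc", 0.0), n, rng)
        i_vals = _lognormal_with_mean_cv(net.neuron.c_m_inh, cv.get("c_m_inh", 0.0), n, rng)
        c_m = np.where(is_e, e_vals, i_vals)
    if "tau_m_exc" in cv or "tau_m_inh" in cv:
        e_vals = _lognormal_with_mean_cv(net.neuron.tau_m, cv.get("tau_m_exc", 0.0), n, rng)
        i_vals = _lognormal_with_mean_cv(net.neuron.tau_m, cv.get("tau_m_inh", 0.0), n, rng)
        tau_m = np.where(is_e, e_vals, i_vals)
    net.v_th_of_neuron = v_th
    net.c_m_of_neuron = c_m
    net.tau_m_of_neuron = tau_m
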