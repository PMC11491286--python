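"""Native spiking simulation engine.

Integrates leaky integrate-and-fire neurons with exponential postsynaptic
currents on a fixed time grid (default 0.1 ms) using the exact propagator of
the linear (V, I) subsystem; threshold crossings emit spikes stamped on the
grid and clamp the membrane at the reset potential for the refractory
period. Every neuron owns an independent counter-based random stream keyed
by (seed, neuron id) that supplies its initial membrane potential and its
external Poisson drive. Because a neuron's stream is consumed independently
of network activity, two simulations with the same seed draw exactly the
same random numbers — the basis of the exactly-paired perturbation protocol.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Population
from .network import NetworkRealization

__all__ = ["SpikeRecord", "simulate", "paired_perturbation_simulate"]


@dataclasses.dataclass
class SpikeRecord:
    """Spike events of one simulation, with population bookkeeping.

    ``times`` (ms) are sorted and grid-aligned; ``senders`` holds neuron ids.
    ``probe`` (optional) is the per-area sum of absolute synaptic currents,
    sampled every millisecond — the raw material of the fMRI BOLD proxy.
    """

    times: np.ndarray  # ms, sorted
    senders: np.ndarray  # neuron ids, int64
    duration: float  # ms
    dt: float  # ms
    populations: list[Population]
    pop_sizes: np.ndarray
    pop_offset: np.ndarray
    pop_of_neuron: np.ndarray
    area_names: list[str]
    seed: int
    probe_times: np.ndarray | None = None  # ms
    probe: np.ndarray | None = None  # (n_areas, n_samples), pA
    voltage_ids: np.ndarray | None = None  # neurons with recorded V
    voltage: np.ndarray | None = None  # (len(voltage_ids), n_steps), mV

    @property
    def n_neurons(self) -> int:
        return self.pop_of_neuron.size

    def population_spikes(self, index: int) -> np.ndarray:
        """Spike times of one population (sorted)."""
        lo, hi = self.pop_offset[index], self.pop_offset[index + 1]
        mask = (self.senders >= lo) & (self.senders < hi)
        return self.times[mask]

    def spike_trains(self, neuron_ids: np.ndarray | None = None) -> dict[int, np.ndarray]:
        """Per-neuron spike-time arrays (only neurons that spiked appear
        unless ``neuron_ids`` is given, in which case all listed neurons do)."""
        order = np.argsort(self.senders, kind="stable")
        senders = self.senders[order]
        times = self.times[order]
        trains: dict[int, np.ndarray] = {}
        if neuron_ids is not None:
            for nid in np.asarray(neuron_ids):
                trains[int(nid)] = np.empty(0)
        bounds = np.searchsorted(senders, np.arange(self.n_neurons + 1))
        for nid in np.unique(senders):
            lo, hi = bounds[nid], bounds[nid + 1]
            trains[int(nid)] = np.sort(times[lo:hi])
        return trains

    def write_gdf(self, path: str | Path) -> None:
        """Write spikes as whitespace-separated ``neuron_id time_ms`` lines."""
        with open(path, "w") as fh:
            for nid, t in zip(self.senders, self.times):
                fh.write(f"{int(nid)} {t:.1f}\n")

    def write_population_index(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "population": [p.label for p in self.populations],
                "area": [p.area for p in self.populations],
                "layer": [p.layer for p in self.populations],
                "ei": [p.ei for p in self.populations],
                "first_id": self.pop_offset[:-1],
                "size": self.pop_sizes,
            }
        ).to_csv(path, index=False)


class SimulationError(RuntimeError):
    pass


def _neuron_streams(seed: int, n_neurons: int) -> list[np.random.Generator]:
    return [
        np.random.Generator(np.random.Philox(key=(seed << 64) + nid))
        for nid in range(n_neurons)
    ]


def simulate(
    net: NetworkRealization,
    duration: float,
    seed: int = 0,
    record_probe: bool = False,
    probe_exclude_drive: bool = False,
    perturbation: tuple[int, float] | None = None,
    chunk_steps: int = 2000,
    dc_current_pa: float | np.ndarray = 0.0,
    record_voltage: np.ndarray | list[int] | None = None,
) -> SpikeRecord:
    """Simulate a network realization for ``duration`` ms.

    ``perturbation = (neuron_id, time_ms)`` lifts that neuron's membrane
    potential above threshold at the given grid time, forcing one extra
    spike; everything else, including every random draw, is unaffected.
    ``dc_current_pa`` adds a constant current (useful for closed-form
    checks); ``record_voltage`` lists neuron ids whose membrane potential is
    stored each step.
    """
    dt = net.delay.dt
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ValueError(f"duration {duration} ms is not a multiple of dt={dt} ms")
    n = net.n_neurons
    if n == 0:
        raise ValueError("network has no neurons")

    p_step = -1
    if perturbation is not None:
        p_id, p_time = perturbation
        if not 0 <= p_id < n:
            raise ValueError(f"invalid perturbation neuron id {p_id}")
        if not 0 <= p_time <= duration:
            raise ValueError("perturbation time outside the simulated interval")
        p_step = int(round(p_time / dt))

    neuron = net.neuron
    is_e = net.is_excitatory()
    v_th = (
        net.v_th_of_neuron
        if net.v_th_of_neuron is not None
        else np.full(n, neuron.v_th)
    )
    c_m = (
        net.c_m_of_neuron
        if net.c_m_of_neuron is not None
        else np.where(is_e, neuron.c_m_exc, neuron.c_m_inh).astype(float)
    )
    tau_m = (
        net.tau_m_of_neuron
        if net.tau_m_of_neuron is not None
        else np.full(n, neuron.tau_m)
    )
    tau_s = neuron.tau_s
    e_l = neuron.e_l
    v_reset = neuron.v_reset
    n_ref = int(round(neuron.tau_r / dt))

    # exact propagator coefficients per neuron
    p_v = np.exp(-dt / tau_m)
    p_i = np.exp(-dt / tau_s)
    with np.errstate(divide="raise"):
        coef = (p_i - p_v) * tau_m * tau_s / (c_m * (tau_s - tau_m))
    dc = np.broadcast_to(np.asarray(dc_current_pa, dtype=float), (n,))
    dc_term = dc * (tau_m / c_m) * (1.0 - p_v)

    # per-neuron external drive
    pop = net.pop_of_neuron
    lam = net.nu_ext_pop[pop] * net.k_ext_pop[pop] * dt * 1e-3  # counts per step
    j_ext_n = net.j_ext_pop[pop]

    streams = _neuron_streams(seed, n)
    v = np.array([g.uniform(v_reset, vt) for g, vt in zip(streams, v_th)])
    i_rec = np.zeros(n)
    i_ext = np.zeros(n)
    refr = np.zeros(n, dtype=np.int32)

    max_delay = int(net.syn_delay.max()) if net.n_synapses else 1
    buf_len = max_delay + 1
    buf = np.zeros((buf_len, n), dtype=np.float32)

    probe_every = max(1, int(round(1.0 / dt)))
    probe_samples: list[np.ndarray] = []
    probe_steps: list[int] = []
    area_of = net.area_of_neuron() if record_probe else None
    n_areas = len(net.area_names)

    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []

    v_ids = None
    v_trace = None
    if record_voltage is not None:
        v_ids = np.asarray(record_voltage, dtype=np.int64)
        v_trace = np.empty((v_ids.size, n_steps), dtype=np.float32)

    indptr, tgt, wgt, dly = net.indptr, net.syn_target, net.syn_weight, net.syn_delay

    counts_chunk = np.empty((n, 0), dtype=np.uint16)
    chunk_start = 0
    for step in range(n_steps):
        k = step - chunk_start
        if k >= counts_chunk.shape[1]:
            m = min(chunk_steps, n_steps - step)
            counts_chunk = np.empty((n, m), dtype=np.uint16)
            for i, g in enumerate(streams):
                if lam[i] > 0:
                    counts_chunk[i] = g.poisson(lam[i], m)
                else:
                    counts_chunk[i] = 0
            chunk_start = step
            k = 0

        slot = step % buf_len
        i_rec += buf[slot]
        buf[slot] = 0.0
        i_ext += counts_chunk[:, k] * j_ext_n

        v = e_l + (v - e_l) * p_v + coef * (i_rec + i_ext) + dc_term
        i_rec *= p_i
        i_ext *= p_i

        in_ref = refr > 0
        if in_ref.any():
            v[in_ref] = v_reset
            refr[in_ref] -= 1

        if step == p_step:
            v[p_id] = v_th[p_id] + 1.0
            refr[p_id] = 0

        spk = v >= v_th
        if spk.any():
            ids = np.where(spk)[0]
            v[ids] = v_reset
            refr[ids] = n_ref
            spike_ids.append(ids.astype(np.int64))
            spike_steps.append(np.full(ids.size, step + 1, dtype=np.int64))
            if net.n_synapses:
                sl = [slice(indptr[i], indptr[i + 1]) for i in ids]
                if sl:
                    idx = np.concatenate([np.arange(s.start, s.stop) for s in sl])
                    if idx.size:
                        arrive = (step + dly[idx].astype(np.int64)) % buf_len
                        np.add.at(buf, (arrive, tgt[idx].astype(np.int64)), wgt[idx])

        if v_trace is not None:
            v_trace[:, step] = v[v_ids]

        if record_probe and (step + 1) % probe_every == 0:
            cur = np.abs(i_rec if probe_exclude_drive else i_rec + i_ext)
            probe_samples.append(np.bincount(area_of, weights=cur, minlength=n_areas))
            probe_steps.append(step + 1)

        if (step + 1) % 10000 == 0 and not np.all(np.isfinite(v)):
            bad = int(np.where(~np.isfinite(v))[0][0])
            raise SimulationError(
                f"non-finite membrane potential for neuron {bad} at t={(step + 1) * dt} ms"
            )

    if spike_ids:
        senders = np.concatenate(spike_ids)
        times = np.concatenate(spike_steps) * dt
        order = np.argsort(times, kind="stable")
        senders, times = senders[order], times[order]
    else:
        senders = np.empty(0, dtype=np.int64)
        times = np.empty(0)

    record = SpikeRecord(
        times=times,
        senders=senders,
        duration=duration,
        dt=dt,
        populations=net.populations,
        pop_sizes=net.pop_sizes,
        pop_offset=net.pop_offset,
        pop_of_neuron=net.pop_of_neuron,
        area_names=net.area_names,
        seed=seed,
    )
    if record_probe:
        record.probe_times = np.array(probe_steps, dtype=float) * dt
        record.probe = np.array(probe_samples).T if probe_samples else np.zeros((n_areas, 0))
    if v_trace is not None:
        record.voltage_ids = v_ids
        record.voltage = v_trace
    return record


def paired_perturbation_simulate(
    net: NetworkRealization,
    duration: float,
    seed: int,
    perturbation: tuple[int, float],
    **kwargs,
) -> tuple[SpikeRecord, SpikeRecord]:
    """Run the exactly-paired control/perturbed protocol.

    Both runs use the same realization, seed and per-neuron random streams,
    so they draw identical random numbers; the only difference is the forced
    extra spike of one neuron. Returns (control, perturbed).
    """
    control = simulate(net, duration, seed=seed, **kwargs)
    perturbed = simulate(net, duration, seed=seed, perturbation=perturbation, **kwargs)
    return control, perturbed
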