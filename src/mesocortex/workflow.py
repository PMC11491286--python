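"""End-to-end workflow helpers built on the library modules.

These functions implement the reproducible pipeline behind the command-line
interface: anatomy -> connectome -> network -> simulation -> analysis, plus
the scan over the inter-areal synaptic scaling factor chi that locates the
best-fitting regime by comparing simulated activity with experimental
references (spike-train summaries and a functional-connectivity matrix,
both supplied as CSV).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (
    bold_proxy_fc,
    compute_rates,
    cv_isi,
    fc_similarity,
    ks_similarity,
    lvr,
    snippet_split,
)
from .anatomy import AnatomyBundle, load_anatomy_bundle
from .config import RunConfig
from .connectome import assemble_connectome
from .network import realize_network
from .params import DelayParams, ExternalDriveParams, NeuronParams, SynapseModelParams
from .simulation import SpikeRecord, simulate
from .synth import synth_anatomy

logger = logging.getLogger(__name__)

__all__ = ["load_or_generate_anatomy", "run_simulation", "activity_summaries", "run_chi_sweep"]


def load_or_generate_anatomy(config: RunConfig) -> AnatomyBundle:
    if config.synthetic:
        bundle, _ = synth_anatomy(
            seed=config.seed_for("anatomy"), n_areas=config.n_areas
        )
        if config.constants_override:
            from .anatomy import ModelConstants

            bundle.constants = ModelConstants(**config.constants_override)
        return bundle
    return load_anatomy_bundle(config.anatomy_files, config.constants_override)


def run_simulation(
    config: RunConfig,
    bundle: AnatomyBundle | None = None,
    chi: float | None = None,
    seed: int | None = None,
    record_probe: bool = True,
) -> SpikeRecord:
    """Build the connectome, realize a scaled network and simulate it."""
    bundle = bundle or load_or_generate_anatomy(config)
    grid, counts = assemble_connectome(bundle)
    synapse = SynapseModelParams(
        chi=chi if chi is not None else config.chi, chi_i=config.chi_i
    )
    net = realize_network(
        counts,
        grid,
        bundle.tracts,
        neuron=NeuronParams(),
        synapse=synapse,
        delay=DelayParams(dt=config.dt),
        drive=ExternalDriveParams(strict_eta=config.strict_eta),
        scale=config.scale,
        seed=config.seed_for("network"),
    )
    sim_seed = seed if seed is not None else config.seed_for("simulation")
    logger.info(
        "simulating %d neurons / %d synapses for %g ms (seed %d)",
        net.n_neurons, net.n_synapses, config.duration, sim_seed,
    )
    return simulate(net, config.duration, seed=sim_seed, record_probe=record_probe)


def activity_summaries(
    record: SpikeRecord,
    config: RunConfig,
    area: str | None = None,
) -> dict[str, np.ndarray]:
    """Neuron-level rate / CV ISI / LvR samples for the comparison area.

    Spike trains of all populations of ``area`` (default: the whole record)
    are pooled, the transient discarded, and the activity split into 5
    snippets mirroring short experimental recordings.
    """
    keep = record.times >= config.transient
    senders, times = record.senders[keep], record.times[keep] - config.transient
    if area is not None:
        a_idx = record.area_names.index(area)
        pop_area = np.array(
            [record.area_names.index(p.area) for p in record.populations]
        )
        mask = pop_area[record.pop_of_neuron[senders]] == a_idx
        senders, times = senders[mask], times[mask]
    trains: dict[int, np.ndarray] = {}
    for nid in np.unique(senders):
        trains[int(nid)] = np.sort(times[senders == nid])
    window = record.duration - config.transient
    snippets = snippet_split(trains, total=window, n=5)
    rates, cvs, lvrs = [], [], []
    for snip in snippets:
        raw, filt = compute_rates(snip, window / 5, config.min_rate_filter)
        rates.extend(filt.values())
        for t in snip.values():
            c = cv_isi(t, config.min_spikes_filter)
            if c is not None:
                cvs.append(c)
            l = lvr(t, config.lvr_refractoriness, config.min_spikes_filter)
            if l is not None:
                lvrs.append(l)
    return {
        "rates": np.asarray(rates),
        "cv_isi": np.asarray(cvs),
        "lvr": np.asarray(lvrs),
    }


@dataclasses.dataclass
class ExperimentalReference:
    """User-supplied comparison data: spike statistics samples and an FC matrix."""

    rates: np.ndarray
    cv_isi: np.ndarray
    lvr: np.ndarray
    fc: np.ndarray

    @classmethod
    def from_csv(cls, spikes_csv: str | Path, fc_csv: str | Path) -> "ExperimentalReference":
        df = pd.read_csv(spikes_csv)
        fc = pd.read_csv(fc_csv, index_col=0).to_numpy(dtype=float)
        return cls(
            rates=df["rate"].dropna().to_numpy(),
            cv_isi=df["cv_isi"].dropna().to_numpy(),
            lvr=df["lvr"].dropna().to_numpy(),
            fc=fc,
        )


def compare_activity(
    record: SpikeRecord,
    reference: ExperimentalReference,
    config: RunConfig,
    area: str | None = None,
) -> dict[str, float]:
    """The five similarity measures of one simulation against the reference."""
    sums = activity_summaries(record, config, area=area)
    fc_sim = bold_proxy_fc(
        record.probe[:, record.probe_times >= config.transient], record.area_names
    )
    pearson, rmse_based = fc_similarity(fc_sim, reference.fc)
    out = {}
    for key in ("rates", "cv_isi", "lvr"):
        sim = sums[key]
        ref = getattr(reference, key if key != "rates" else "rates")
        out[f"ks_{key}"] = (
            ks_similarity(sim, ref) if sim.size and ref.size else float("nan")
        )
    out["fc_pearson"] = pearson
    out["fc_rmse_based"] = rmse_based
    return out


def run_chi_sweep(
    config: RunConfig,
    chi_values: list[float],
    seeds: list[int],
    reference: ExperimentalReference,
    bundle: AnatomyBundle | None = None,
    area: str | None = None,
) -> pd.DataFrame:
    """Similarity measures as a function of the inter-areal scaling chi.

    For each chi the network is rebuilt and simulated once per seed; the
    table reports mean and SD across seeds of the five similarity measures.
    """
    if not chi_values:
        raise ValueError("need at least one chi value")
    bundle = bundle or load_or_generate_anatomy(config)
    rows = []
    for chi in chi_values:
        per_seed = []
        for seed in seeds:
            record = run_simulation(config, bundle=bundle, chi=chi, seed=seed)
            per_seed.append(compare_activity(record, reference, config, area=area))
        keys = per_seed[0].keys()
        row: dict[str, float] = {"chi": chi}
        for k in keys:
            vals = np.array([d[k] for d in per_seed], dtype=float)
            row[f"{k}_mean"] = float(np.nanmean(vals))
            row[f"{k}_sd"] = float(np.nanstd(vals, ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)
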