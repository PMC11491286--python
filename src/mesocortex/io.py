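"""Readers and writers for the package's tabular artifacts.

Connectomes are exchanged as long-format CSV (one row per population pair
with a nonzero synapse count) plus a per-population external-drive table;
spike data as GDF-style text ("neuron_id time_ms" per line) with a
population-index CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .areas import POPULATION_LABELS
from .connectome import Population, PopulationGrid, SynapseCounts

__all__ = [
    "write_connectome_csv",
    "read_connectome_csv",
    "read_gdf",
    "write_probe_csv",
]


def write_connectome_csv(
    grid: PopulationGrid,
    counts: SynapseCounts,
    directory: str | Path,
) -> dict[str, Path]:
    """Write synapses.csv (long format), external_drive.csv, populations.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t_idx, s_idx = np.nonzero(counts.internal)
    pops = grid.populations
    syn = pd.DataFrame(
        {
            "target_area": [pops[i].area for i in t_idx],
            "target_layer": [pops[i].layer for i in t_idx],
            "target_ei": [pops[i].ei for i in t_idx],
            "source_area": [pops[j].area for j in s_idx],
            "source_layer": [pops[j].layer for j in s_idx],
            "source_ei": [pops[j].ei for j in s_idx],
            "n_synapses": counts.internal[t_idx, s_idx],
        }
    )
    ext = pd.DataFrame(
        {
            "area": [p.area for p in pops],
            "layer": [p.layer for p in pops],
            "ei": [p.ei for p in pops],
            "n_synapses": counts.external_drive,
            "n_neurons": grid.sizes,
        }
    )
    paths = {
        "synapses": directory / "synapses.csv",
        "external_drive": directory / "external_drive.csv",
        "populations": directory / "populations.csv",
    }
    syn.to_csv(paths["synapses"], index=False)
    ext.to_csv(paths["external_drive"], index=False)
    pd.DataFrame(
        {
            "area": [p.area for p in pops],
            "layer": [p.layer for p in pops],
            "ei": [p.ei for p in pops],
            "n_neurons": grid.sizes,
        }
    ).to_csv(paths["populations"], index=False)
    return paths


def read_connectome_csv(directory: str | Path) -> tuple[PopulationGrid, SynapseCounts]:
    """Inverse of :func:`write_connectome_csv` (bookkeeping is not restored)."""
    directory = Path(directory)
    pops_df = pd.read_csv(directory / "populations.csv")
    area_names = list(dict.fromkeys(pops_df["area"]))
    populations = [
        Population(str(r.area), str(r.layer), str(r.ei)) for r in pops_df.itertuples()
    ]
    grid = PopulationGrid(
        populations=populations,
        sizes=pops_df["n_neurons"].to_numpy(dtype=np.int64),
        area_names=area_names,
    )
    index = {(p.area, p.layer, p.ei): i for i, p in enumerate(populations)}
    n = len(populations)
    internal = np.zeros((n, n), dtype=np.int64)
    syn = pd.read_csv(directory / "synapses.csv")
    for r in syn.itertuples():
        t = index[(str(r.target_area), str(r.target_layer), str(r.target_ei))]
        s = index[(str(r.source_area), str(r.source_layer), str(r.source_ei))]
        internal[t, s] = int(r.n_synapses)
    ext_df = pd.read_csv(directory / "external_drive.csv")
    external = np.zeros(n, dtype=np.int64)
    for r in ext_df.itertuples():
        external[index[(str(r.area), str(r.layer), str(r.ei))]] = int(r.n_synapses)
    return grid, SynapseCounts(internal=internal, external_drive=external, bookkeeping={})


def read_gdf(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a GDF-style spike file; returns (senders, times_ms), time-sorted."""
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    senders = data[:, 0].astype(np.int64)
    times = data[:, 1].astype(float)
    order = np.argsort(times, kind="stable")
    return senders[order], times[order]


def write_probe_csv(probe_times: np.ndarray, probe: np.ndarray, area_names: list[str], path: str | Path) -> None:
    """Per-area summed |synaptic current| traces as CSV (time + one column per area)."""
    df = pd.DataFrame(probe.T, columns=area_names)
    df.insert(0, "time_ms", probe_times)
    df.to_csv(path, index=False)
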