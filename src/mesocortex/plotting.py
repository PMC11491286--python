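"""Figure helpers: raster plots, population-statistics box plots, FC heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .simulation import SpikeRecord

__all__ = ["plot_raster", "plot_fc_matrix", "plot_population_stats"]


def plot_raster(
    record: SpikeRecord,
    area: str,
    fraction: float = 0.025,
    t_range: tuple[float, float] | None = None,
    path: str | Path | None = None,
    seed: int = 0,
):
    """Raster of a subsample of one area's neurons (excitatory blue, inhibitory red)."""
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(6, 4))
    y0 = 0
    for p_idx, pop in enumerate(record.populations):
        if pop.area != area or record.pop_sizes[p_idx] == 0:
            continue
        lo, hi = record.pop_offset[p_idx], record.pop_offset[p_idx + 1]
        n_sub = max(1, int(fraction * (hi - lo)))
        chosen = np.sort(rng.choice(np.arange(lo, hi), size=n_sub, replace=False))
        remap = {int(nid): y0 + k for k, nid in enumerate(chosen)}
        mask = np.isin(record.senders, chosen)
        t = record.times[mask]
        y = np.array([remap[int(s)] for s in record.senders[mask]])
        if t_range is not None:
            sel = (t >= t_range[0]) & (t <= t_range[1])
            t, y = t[sel], y[sel]
        ax.plot(t, y, ".", ms=1, color="tab:blue" if pop.ei == "E" else "tab:red")
        y0 += n_sub
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    ax.set_title(area)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_fc_matrix(fc: np.ndarray, area_names: list[str], path: str | Path | None = None):
    """Functional-connectivity heatmap."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(fc, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(area_names)))
    ax.set_xticklabels(area_names, rotation=90, fontsize=5)
    ax.set_yticks(range(len(area_names)))
    ax.set_yticklabels(area_names, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_population_stats(
    stats: dict[str, dict[str, float]],
    key: str,
    path: str | Path | None = None,
):
    """Distribution of one population-averaged statistic across areas,
    grouped by population label (layer and E/I)."""
    groups: dict[str, list[float]] = {}
    for label, d in stats.items():
        pop = label.split(":", 1)[1]
        v = d.get(key)
        if v is not None and np.isfinite(v):
            groups.setdefault(pop, []).append(v)
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = list(groups)
    ax.boxplot([groups[l] for l in labels], tick_labels=labels)
    ax.set_ylabel(key)
    ax.tick_params(axis="x", rotation=45)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
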