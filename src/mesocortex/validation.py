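"""Structural validation statistics of an assembled mesoconnectome.

These reproduce the checks applied to the model against features that were
not built in: the approximately log-normal distribution of synapse counts
over population pairs, the exponential decay of area-level connectivity with
fiber distance, the feedforward/feedback asymmetry of outdegrees and of the
number of target areas, and the small-world path statistics of the directed
population graph (unweighted and mean-delay-weighted).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra, shortest_path

from .areas import POPULATION_LABELS
from .connectome import ConnectomeError, PopulationGrid, SynapseCounts

__all__ = ["ValidationReport", "validate_connectome", "fit_distance_decay", "fit_lognormal"]


@dataclasses.dataclass
class ValidationReport:
    lognormal_mu: float  # mean of log10 synapse counts over nonzero pairs
    lognormal_sigma: float
    decay_constant_mm: float
    decay_r_squared: float
    outdegree_mean: dict[str, float]  # per direction class FF/LAT/FB
    target_area_mean: dict[str, float]  # outdegree>100 filter
    path_length_max: int
    path_length_hist: dict[int, int]
    delay_path_max_ms: float
    delay_path_hist: dict[str, int]  # "lo-hi" ms bins -> pair count

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["path_length_hist"] = {str(k): v for k, v in self.path_length_hist.items()}
        Path(path).write_text(json.dumps(data, indent=2))


def fit_lognormal(counts: np.ndarray) -> tuple[float, float]:
    """Mean and SD of log10 of the nonzero synapse counts (population pairs)."""
    nz = counts[counts > 0]
    if nz.size < 3:
        raise ConnectomeError("need at least 3 nonzero pairs for the log-normal fit")
    logs = np.log10(nz.astype(float))
    return float(logs.mean()), float(logs.std(ddof=0))


def fit_distance_decay(
    area_counts: np.ndarray, fiber_length: np.ndarray
) -> tuple[float, float]:
    """Exponential distance decay of inter-areal synapse counts.

    Ordinary least squares of ln(count) on fiber length over ordered area
    pairs with nonzero count; returns (decay constant in mm = -1/slope, R^2).
    """
    n = area_counts.shape[0]
    off = ~np.eye(n, dtype=bool)
    mask = off & (area_counts > 0)
    if mask.sum() < 3:
        raise ConnectomeError("need at least 3 nonzero area pairs for the decay fit")
    x = fiber_length[mask]
    y = np.log(area_counts[mask].astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    if slope >= 0:
        # no decay measurable (flat or increasing): infinite decay constant
        return float("inf"), float(r2)
    return float(-1.0 / slope), float(r2)


def _direction_class(sln: float, ff: float, fb: float) -> str:
    # boundary values belong to the lateral class
    if sln > ff:
        return "FF"
    if sln < fb:
        return "FB"
    return "LAT"


def validate_connectome(
    counts: SynapseCounts,
    grid: PopulationGrid,
    tracts,
    slns: np.ndarray,
    delays,
    outdegree_filter: float = 100.0,
    ff_threshold: float = 0.65,
    fb_threshold: float = 0.35,
) -> ValidationReport:
    """Compute all structural validation statistics of a mesoconnectome.

    ``slns`` is the (source area, target area) SLN matrix used for direction
    classification; ``delays`` supplies the mean local delays and conduction
    velocity for the delay-weighted path analysis.
    """
    n_areas = len(grid.area_names)
    n_pop = grid.n_populations
    internal = counts.internal
    area_index = {name: i for i, name in enumerate(grid.area_names)}
    pop_area = np.array([area_index[p.area] for p in grid.populations])

    mu, sigma = fit_lognormal(internal)

    # area-level counts [source, target]: sum over population blocks
    onehot = np.eye(n_areas)[pop_area]  # (n_pop, n_areas)
    area_counts = (onehot.T @ internal.T @ onehot).astype(np.int64)
    inter = area_counts.copy()
    np.fill_diagonal(inter, 0)
    lam, r2 = fit_distance_decay(inter, tracts.fiber_length)

    # outdegrees per (source population, target area), inter-areal only
    sizes = grid.sizes.astype(float)
    out_by_class: dict[str, list[float]] = {"FF": [], "LAT": [], "FB": []}
    # per source population and class: number of target areas above filter
    n_targets: dict[str, np.ndarray] = {
        c: np.zeros(n_pop) for c in ("FF", "LAT", "FB")
    }
    # synapses from each source population into each target area
    proj_ta = internal.T @ onehot  # (n_pop_source, n_areas_target)
    for s_idx in range(n_pop):
        if sizes[s_idx] == 0:
            continue
        s_area = pop_area[s_idx]
        for t_area in range(n_areas):
            if t_area == s_area:
                continue
            syn = proj_ta[s_idx, t_area]
            if syn == 0:
                continue
            outdeg = syn / sizes[s_idx]
            cls = _direction_class(slns[s_area, t_area], ff_threshold, fb_threshold)
            out_by_class[cls].append(outdeg)
            if outdeg > outdegree_filter:
                n_targets[cls][s_idx] += 1
    outdegree_mean = {
        c: (float(np.mean(v)) if v else float("nan")) for c, v in out_by_class.items()
    }
    target_area_mean = {}
    for c, vec in n_targets.items():
        nz = vec[vec > 0]
        target_area_mean[c] = float(nz.mean()) if nz.size else float("nan")

    # directed population graph restricted to existing populations
    exists = grid.exists
    idx = np.where(exists)[0]
    sub = internal[np.ix_(idx, idx)]
    adj = (sub > 0)
    n = idx.size
    # unweighted shortest paths (edges source -> target); csgraph uses
    # row -> col, our matrix is [target, source], so transpose.
    graph = csr_matrix(adj.T.astype(np.int8))
    dist = shortest_path(graph, method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = dist[off][np.isfinite(dist[off])]
    lengths, cnts = np.unique(finite.astype(int), return_counts=True)
    path_hist = {int(l): int(c) for l, c in zip(lengths, cnts)}
    path_max = int(finite.max()) if finite.size else 0

    # mean-delay-weighted Dijkstra
    src_area = pop_area[idx]
    pop_is_e = np.array([p.ei == "E" for p in grid.populations])
    src_is_e = pop_is_e[idx]
    w = np.zeros_like(sub, dtype=float)
    fiber = tracts.fiber_length
    for j in range(n):  # source
        for i in range(n):  # target
            if not adj[i, j]:
                continue
            if src_area[i] == src_area[j]:
                w[i, j] = delays.d_e if src_is_e[j] else delays.d_i
            else:
                w[i, j] = fiber[src_area[j], src_area[i]] / delays.v_t
    wgraph = csr_matrix(w.T)
    ddist = dijkstra(wgraph)
    dfinite = ddist[off][np.isfinite(ddist[off])]
    delay_max = float(dfinite.max()) if dfinite.size else 0.0
    bins = np.arange(0.0, np.ceil(delay_max / 5.0) * 5.0 + 5.0, 5.0)
    hist, edges = np.histogram(dfinite, bins=bins)
    delay_hist = {
        f"{edges[i]:.0f}-{edges[i + 1]:.0f}": int(h) for i, h in enumerate(hist)
    }

    return ValidationReport(
        lognormal_mu=mu,
        lognormal_sigma=sigma,
        decay_constant_mm=lam,
        decay_r_squared=r2,
        outdegree_mean=outdegree_mean,
        target_area_mean=target_area_mean,
        path_length_max=path_max,
        path_length_hist=path_hist,
        delay_path_max_ms=delay_max,
        delay_path_hist=delay_hist,
    )
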