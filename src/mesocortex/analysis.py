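"""Activity statistics, similarity measures and emergent-dynamics analyses.

Implements the spike-train statistics used to compare the model with
electrophysiological recordings (firing rates, CV ISI, revised local
variation LvR, pairwise correlations), the Kolmogorov-Smirnov similarity of
distributions, the fMRI functional-connectivity proxy based on summed
absolute synaptic currents with its two similarity measures, and the
analysis of single-spike perturbation propagation. The temporal-hierarchy
estimator lives in :mod:`mesocortex.hierarchy`.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .simulation import SpikeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "compute_rates",
    "cv_isi",
    "lvr",
    "pairwise_correlations",
    "ks_similarity",
    "snippet_split",
    "bold_proxy_fc",
    "fc_similarity",
    "population_statistics",
    "perturbation_propagation",
    "PropagationTrace",
    "MIN_RATE_FILTER",
    "MIN_SPIKES_FILTER",
]

#: Default comparison filters: neurons below 0.5 spikes/s are excluded from
#: rate comparisons; irregularity measures need at least 10 spikes.
MIN_RATE_FILTER = 0.5
MIN_SPIKES_FILTER = 10


def compute_rates(
    trains: dict[int, np.ndarray],
    window: float,
    min_rate_filter: float = MIN_RATE_FILTER,
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-neuron firing rates over ``window`` ms.

    Returns ``(raw, filtered)``: raw rates for every neuron (silent neurons
    contribute 0), and the subset at or above the filter used for
    comparisons with recordings.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    raw = {nid: len(t) / (window * 1e-3) for nid, t in trains.items()}
    filtered = {nid: r for nid, r in raw.items() if r >= min_rate_filter}
    return raw, filtered


def cv_isi(train: np.ndarray, min_spikes: int = MIN_SPIKES_FILTER) -> float | None:
    """Coefficient of variation of the interspike intervals.

    0 for a perfectly regular train, 1 for a Poisson process. Trains with
    fewer than ``min_spikes`` spikes are excluded (returns None).
    """
    train = np.asarray(train, dtype=float)
    if train.size < min_spikes:
        return None
    isi = np.diff(np.sort(train))
    m = isi.mean()
    if m == 0:
        return 0.0
    return float(isi.std(ddof=0) / m)


def lvr(
    train: np.ndarray,
    refractoriness: float = 5.0,
    min_spikes: int = MIN_SPIKES_FILTER,
) -> float | None:
    """Revised local variation of a spike train.

    LvR = 3/(n-1) * sum_i [1 - 4 I_i I_{i+1} / (I_i + I_{i+1})^2]
                        * [1 + 4 R / (I_i + I_{i+1})]

    over consecutive interspike-interval pairs; R is the refractoriness
    constant in ms (R = 0 recovers the plain local variation, which is 1
    for a Poisson process and 0 for a regular train). Corrects for slow
    firing-rate fluctuations, which inflate the CV ISI but not LvR.
    """
    train = np.asarray(train, dtype=float)
    if train.size < min_spikes:
        return None
    isi = np.diff(np.sort(train))
    a, b = isi[:-1], isi[1:]
    s = a + b
    if np.any(s == 0):
        # coincident spikes: drop degenerate pairs
        keep = s > 0
        a, b, s = a[keep], b[keep], s[keep]
        if s.size == 0:
            return 0.0
    terms = (1.0 - 4.0 * a * b / s**2) * (1.0 + 4.0 * refractoriness / s)
    return float(3.0 * terms.sum() / (isi.size - 1))


def pairwise_correlations(
    trains: dict[int, np.ndarray],
    duration: float,
    subsample_size: int = 2000,
    bin_ms: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Pearson correlations of binned spike counts for a random subsample.

    Neurons are subsampled without replacement (the whole set if smaller
    than ``subsample_size``); zero-variance trains are dropped with a log
    message. Returns the flat array of correlation coefficients over all
    remaining pairs.
    """
    ids = sorted(trains)
    if len(ids) < 2:
        raise ValueError("need at least two neurons")
    rng = np.random.default_rng(seed)
    if len(ids) > subsample_size:
        ids = list(rng.choice(ids, size=subsample_size, replace=False))
    edges = np.arange(0.0, duration + bin_ms, bin_ms)
    mat = np.stack([np.histogram(trains[i], bins=edges)[0] for i in ids]).astype(float)
    var = mat.var(axis=1)
    if np.any(var == 0):
        logger.info("dropping %d zero-variance trains from correlations", int((var == 0).sum()))
        mat = mat[var > 0]
    if mat.shape[0] < 2:
        return np.empty(0)
    cc = np.corrcoef(mat)
    iu = np.triu_indices(cc.shape[0], k=1)
    return cc[iu]


def ks_similarity(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """1 - Kolmogorov-Smirnov distance between two empirical distributions.

    1 means identical distributions, 0 means fully disjoint supports.
    Symmetric and invariant under common strictly monotone transforms.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    return float(1.0 - stats.ks_2samp(a, b, method="asymp").statistic)


def snippet_split(
    trains: dict[int, np.ndarray],
    total: float = 10_000.0,
    n: int = 5,
) -> list[dict[int, np.ndarray]]:
    """Cut spike trains into ``n`` contiguous equal windows, times re-zeroed.

    Mirrors the comparison protocol in which 10 s of simulated activity are
    matched against short recordings by splitting them into 5 snippets.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    width = total / n
    out: list[dict[int, np.ndarray]] = []
    for k in range(n):
        lo, hi = k * width, (k + 1) * width
        out.append(
            {
                nid: t[(t >= lo) & (t < hi)] - lo
                for nid, t in trains.items()
            }
        )
    return out


def bold_proxy_fc(probe: np.ndarray, area_names: list[str] | None = None) -> np.ndarray:
    """Functional connectivity of the BOLD proxy.

    ``probe`` is the (n_areas, n_samples) matrix of per-area summed absolute
    synaptic currents; returns the Pearson correlation matrix (symmetric,
    unit diagonal). A constant trace makes the correlation undefined and is
    reported as an error naming the area.
    """
    probe = np.asarray(probe, dtype=float)
    if probe.ndim != 2 or probe.shape[0] < 2:
        raise ValueError("need at least two area traces")
    var = probe.var(axis=1)
    if np.any(var == 0):
        idx = int(np.where(var == 0)[0][0])
        name = area_names[idx] if area_names else str(idx)
        raise ValueError(f"area {name!r} has a constant BOLD-proxy trace")
    fc = np.corrcoef(probe)
    np.fill_diagonal(fc, 1.0)
    return fc


def fc_similarity(fc_sim: np.ndarray, fc_exp: np.ndarray) -> tuple[float, float]:
    """Similarity of two functional-connectivity matrices.

    Returns ``(pearson, rmse_based)``, both computed over off-diagonal
    entries only: the Pearson correlation of the entries, and
    exp(-RMSE / sigma_exp) with sigma_exp the SD of the experimental
    off-diagonal FC (1 = identical, smaller = less similar; sensitive to
    absolute FC values where the Pearson measure is not).
    """
    fc_sim = np.asarray(fc_sim, dtype=float)
    fc_exp = np.asarray(fc_exp, dtype=float)
    if fc_sim.shape != fc_exp.shape or fc_sim.ndim != 2:
        raise ValueError("FC matrices must have identical square shapes")
    off = ~np.eye(fc_sim.shape[0], dtype=bool)
    x, y = fc_sim[off], fc_exp[off]
    pearson = float(np.corrcoef(x, y)[0, 1])
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    sigma = float(y.std(ddof=0))
    if sigma == 0:
        raise ValueError("experimental FC has zero off-diagonal variance")
    return pearson, float(np.exp(-rmse / sigma))


def population_statistics(
    record: SpikeRecord,
    transient: float = 2500.0,
    lvr_refractoriness: float = 5.0,
    corr_subsample: int = 2000,
    corr_bin_ms: float = 1.0,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Population-averaged rate, CV ISI, LvR and pairwise correlation.

    Spikes before ``transient`` ms are discarded. Returns a mapping
    population label -> statistics dict (NaN where no neuron passes the
    respective filter).
    """
    window = record.duration - transient
    if window <= 0:
        raise ValueError("transient longer than the simulation")
    out: dict[str, dict[str, float]] = {}
    for p_idx, pop in enumerate(record.populations):
        size = int(record.pop_sizes[p_idx])
        if size == 0:
            continue
        lo, hi = record.pop_offset[p_idx], record.pop_offset[p_idx + 1]
        mask = (record.senders >= lo) & (record.senders < hi) & (record.times >= transient)
        ids = record.senders[mask]
        times = record.times[mask] - transient
        trains: dict[int, np.ndarray] = {int(n): np.empty(0) for n in range(lo, hi)}
        order = np.argsort(ids, kind="stable")
        ids_s, times_s = ids[order], times[order]
        bounds = np.searchsorted(ids_s, np.arange(lo, hi + 1))
        for j, nid in enumerate(range(lo, hi)):
            trains[nid] = np.sort(times_s[bounds[j]:bounds[j + 1]])
        raw, _ = compute_rates(trains, window)
        cvs = [c for t in trains.values() if (c := cv_isi(t)) is not None]
        lvrs = [l for t in trains.values() if (l := lvr(t, lvr_refractoriness)) is not None]
        try:
            corr = pairwise_correlations(
                trains, window, corr_subsample, corr_bin_ms, seed=seed + p_idx
            )
        except ValueError:
            corr = np.empty(0)
        out[pop.label] = {
            "rate_mean": float(np.mean(list(raw.values()))),
            "cv_isi_mean": float(np.mean(cvs)) if cvs else float("nan"),
            "lvr_mean": float(np.mean(lvrs)) if lvrs else float("nan"),
            "corr_mean": float(corr.mean()) if corr.size else float("nan"),
        }
    return out


# ---------------------------------------------------------------------------
# single-spike perturbation propagation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PropagationTrace:
    """Result of the exactly-paired single-spike perturbation protocol.

    ``first_diff_time_ms`` maps population label -> time of the first
    spike-count difference (NaN if none); ``area_first_diff_ms`` aggregates
    to areas (earliest population). ``mean_ms``/``sd_ms`` summarize the
    per-area times relative to the perturbation.
    """

    bin_ms: float
    perturbation_time: float
    first_diff_time_ms: dict[str, float]
    area_first_diff_ms: dict[str, float]
    mean_ms: float
    sd_ms: float
    no_propagation: bool

    def binary_series(self, duration: float) -> dict[str, np.ndarray]:
        """Per-population 0/1 indicator over time (1 once a difference has
        occurred), in ``bin_ms`` bins — monotone by construction."""
        n_bins = int(round(duration / self.bin_ms))
        out = {}
        for label, t in self.first_diff_time_ms.items():
            series = np.zeros(n_bins, dtype=np.int8)
            if np.isfinite(t):
                series[int(round(t / self.bin_ms)) - 1:] = 1
            out[label] = series
        return out


def perturbation_propagation(
    control: SpikeRecord,
    perturbed: SpikeRecord,
    perturbation_time: float = 0.0,
) -> PropagationTrace:
    """Track where and when a single-spike perturbation alters activity.

    Counts each population's spikes in simulation-step bins (0.1 ms) in
    both runs and takes the earliest bin with a nonzero count difference;
    per area, the earliest of its populations. Identical records yield an
    empty trace flagged ``no_propagation``.
    """
    if control.duration != perturbed.duration or control.dt != perturbed.dt:
        raise ValueError("records are not from a matched pair")
    dt = control.dt
    n_bins = int(round(control.duration / dt))
    first: dict[str, float] = {}
    area_first: dict[str, float] = {a: np.inf for a in control.area_names}
    for p_idx, pop in enumerate(control.populations):
        if control.pop_sizes[p_idx] == 0:
            continue
        tc = control.population_spikes(p_idx)
        tp = perturbed.population_spikes(p_idx)
        hc = np.bincount(
            np.clip((np.round(tc / dt)).astype(int) - 1, 0, n_bins - 1), minlength=n_bins
        )
        hp = np.bincount(
            np.clip((np.round(tp / dt)).astype(int) - 1, 0, n_bins - 1), minlength=n_bins
        )
        diff = np.nonzero(hc != hp)[0]
        t = (diff[0] + 1) * dt if diff.size else np.inf
        first[pop.label] = t
        area_first[pop.area] = min(area_first[pop.area], t)

    finite = {a: t for a, t in area_first.items() if np.isfinite(t)}
    if not finite:
        return PropagationTrace(
            bin_ms=dt,
            perturbation_time=perturbation_time,
            first_diff_time_ms={k: np.nan for k in first},
            area_first_diff_ms={k: np.nan for k in area_first},
            mean_ms=float("nan"),
            sd_ms=float("nan"),
            no_propagation=True,
        )
    rel = np.array(list(finite.values())) - perturbation_time
    return PropagationTrace(
        bin_ms=dt,
        perturbation_time=perturbation_time,
        first_diff_time_ms={k: (v if np.isfinite(v) else np.nan) for k, v in first.items()},
        area_first_diff_ms={k: (v if np.isfinite(v) else np.nan) for k, v in area_first.items()},
        mean_ms=float(rel.mean()),
        sd_ms=float(rel.std(ddof=0)),
        no_propagation=False,
    )
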