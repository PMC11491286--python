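"""Mesoconnectome construction.

Turns an :class:`~mesocortex.anatomy.AnatomyBundle` into the population-level
synapse-count matrix of the model. The construction proceeds per area:

1. neuron numbers per layer (density x thickness x column surface), split into
   excitatory/inhibitory populations;
2. a synapse budget per area (synapse volume density x column volume);
3. a split into local and non-local synapses via the white-matter scaling
   rule calibrated on macaque tracing data;
4. a split of the local budget into column-internal synapses and synapses
   from the rest of the area, via cylindrical integrals of the exponential
   connection profile;
5. internal synapses distributed over population pairs proportionally to a
   layered-microcircuit blueprint; external local synapses become per-
   population external-drive synapse counts;
6. non-local synapses distributed over source areas by relative streamline
   counts, over source populations by the predicted laminar origin (SLN),
   and over target populations by SLN-dependent laminar target patterns,
   dendritic morphology, and E/I target probabilities (with a fixed 93%
   excitatory share for feedback projections).

All integer allocations use largest-remainder rounding so that every child
partition sums exactly to its parent budget.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm

from .anatomy import AnatomyBundle, AnatomyError, AreaAnatomy, DendriticProfile, LocalBlueprint, ModelConstants, SLNFitParams
from .areas import LAYERS, POPULATION_LABELS, SYNAPSE_LAYERS
from .geometry import column_density_integrals

__all__ = [
    "Population",
    "PopulationGrid",
    "SynapseCounts",
    "ConnectomeError",
    "allocate_integers",
    "compute_population_sizes",
    "compute_area_synapse_budget",
    "nonlocal_fraction",
    "split_synapse_budget",
    "distribute_internal",
    "distribute_external_drive",
    "allocate_longrange_sources",
    "predict_sln",
    "sln_matrix",
    "laminar_source_counts",
    "laminar_target_distribution",
    "resolve_postsynaptic_targets",
    "assemble_connectome",
]


class ConnectomeError(ValueError):
    """Raised when a connectome construction step receives invalid input."""


@dataclasses.dataclass(frozen=True)
class Population:
    area: str
    layer: str  # one of "2/3", "4", "5", "6"
    ei: str  # "E" or "I"

    @property
    def label(self) -> str:
        return f"{self.area}:{self.layer}{self.ei}"


@dataclasses.dataclass
class PopulationGrid:
    """Ordered populations (area-major, layer, E/I) with integer neuron counts.

    Populations with zero neurons (absent layers of agranular areas) are
    retained so that matrix indices are uniform: every area contributes the
    full set of eight slots.
    """

    populations: list[Population]
    sizes: np.ndarray  # int64
    area_names: list[str]

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if len(self.populations) != self.sizes.size:
            raise ConnectomeError("populations and sizes length mismatch")
        self._index = {
            (p.area, p.layer, p.ei): i for i, p in enumerate(self.populations)
        }

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def exists(self) -> np.ndarray:
        """Boolean mask of populations with at least one neuron."""
        return self.sizes > 0

    def index(self, area: str, layer: str, ei: str) -> int:
        return self._index[(area, layer, ei)]

    def area_slice(self, area: str) -> slice:
        i = self.area_names.index(area) * len(POPULATION_LABELS)
        return slice(i, i + len(POPULATION_LABELS))

    def area_sizes(self, area: str) -> np.ndarray:
        return self.sizes[self.area_slice(area)]

    @property
    def total_neurons(self) -> int:
        return int(self.sizes.sum())


@dataclasses.dataclass
class SynapseCounts:
    """The mesoconnectome: integer synapse counts per population pair.

    ``internal[target, source]`` covers both within-area and inter-areal
    synapses whose presynaptic neuron is simulated; ``external_drive`` holds
    per-population synapse counts from non-simulated (Poisson) sources.
    ``bookkeeping`` records per-area budgets for conservation checks.
    """

    internal: np.ndarray  # (n_pop, n_pop) int64, [target, source]
    external_drive: np.ndarray  # (n_pop,) int64
    bookkeeping: dict[str, dict[str, int]]

    @property
    def total_synapses(self) -> int:
        return int(self.internal.sum() + self.external_drive.sum())


# ---------------------------------------------------------------------------
# integer allocation
# ---------------------------------------------------------------------------

def allocate_integers(total: int, weights: np.ndarray) -> np.ndarray:
    """Split ``total`` into integers proportional to ``weights``.

    Nearest-integer rounding with largest-remainder reconciliation: the
    result sums to ``total`` exactly and each entry differs from the ideal
    proportional share by less than 1.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ConnectomeError(f"cannot allocate negative total {total}")
    if np.any(weights < 0):
        raise ConnectomeError("allocation weights must be nonnegative")
    wsum = weights.sum()
    if wsum <= 0:
        if total == 0:
            return np.zeros(weights.shape, dtype=np.int64)
        raise ConnectomeError("all allocation weights are zero but total > 0")
    ideal = weights / wsum * total
    base = np.floor(ideal).astype(np.int64)
    remainder = int(total - base.sum())
    if remainder > 0:
        frac = ideal - base
        order = np.argsort(-frac, kind="stable")
        base[order[:remainder]] += 1
    return base


# ---------------------------------------------------------------------------
# neuron and synapse budgets
# ---------------------------------------------------------------------------

def compute_population_sizes(bundle: AnatomyBundle) -> PopulationGrid:
    """Neuron counts per (area, layer, E/I) population.

    Per layer, N = round(rho_neuron * h_layer * A_column); the excitatory
    count is round(N * f_E) and the inhibitory count the remainder.
    """
    a_col = bundle.constants.column_area
    populations: list[Population] = []
    sizes: list[int] = []
    for area in bundle.areas:
        for layer in LAYERS:
            n = int(round(area.neuron_density[layer] * area.layer_thickness[layer] * a_col))
            n_e = int(round(n * area.excitatory_fraction[layer]))
            populations.append(Population(area.name, layer, "E"))
            sizes.append(n_e)
            populations.append(Population(area.name, layer, "I"))
            sizes.append(n - n_e)
    return PopulationGrid(
        populations=populations,
        sizes=np.array(sizes, dtype=np.int64),
        area_names=[a.name for a in bundle.areas],
    )


def compute_area_synapse_budget(bundle: AnatomyBundle, area: str | AreaAnatomy) -> int:
    """Total synapse budget of an area: rho_synapse * A_column * total thickness."""
    if isinstance(area, str):
        area = bundle.areas[bundle.area_index(area)]
    c = bundle.constants
    return int(round(c.rho_synapse * c.column_area * area.total_thickness))


def nonlocal_fraction(constants: ModelConstants) -> float:
    """Fraction of synapses from long-range (white-matter) projections.

    The fraction of neurons sending axons into the white matter scales with
    the total gray-matter neuron count N as N^(-scaling_exponent); the
    proportionality constant is fixed by the calibration point
    (calib_fraction at calib_neurons). The fraction of neurons is assumed to
    equal the fraction of synapses.
    """
    c = constants
    return c.calib_fraction * (c.calib_neurons / c.human_neurons) ** c.scaling_exponent


def split_synapse_budget(
    n_total: int,
    f_nonlocal: float,
    rho_internal: float,
    rho_external: float,
) -> tuple[int, int, int]:
    """Split an area budget into (N_internal, N_external, N_nonlocal).

    N_nonlocal = round(f * N_total); the local remainder is split between
    column-internal synapses and synapses from the rest of the area in
    proportion to the two connection densities, conserving the local budget
    exactly.
    """
    if n_total < 0 or not 0 <= f_nonlocal <= 1:
        raise ConnectomeError("invalid budget or nonlocal fraction")
    if rho_internal < 0 or rho_external < 0:
        raise ConnectomeError("densities must be nonnegative")
    n_nonlocal = int(round(f_nonlocal * n_total))
    n_local = n_total - n_nonlocal
    n_int, n_ext = allocate_integers(n_local, np.array([rho_internal, rho_external]))
    return int(n_int), int(n_ext), n_nonlocal


def distribute_internal(
    blueprint: LocalBlueprint,
    area_sizes: np.ndarray,
    n_internal: int,
) -> np.ndarray:
    """Distribute a column's internal synapses over the 8x8 population pairs.

    entry[target, source] is proportional to N_source * q[target, source] *
    N_target, preserving the blueprint's relative synapse count per neuron
    pair; populations with zero neurons receive and send nothing (absent
    layer-4 populations of agranular areas are handled automatically).
    """
    sizes = np.asarray(area_sizes, dtype=float)
    if sizes.shape != (len(POPULATION_LABELS),):
        raise ConnectomeError(f"expected {len(POPULATION_LABELS)} population sizes")
    weights = sizes[None, :] * blueprint.q_pd * sizes[:, None]
    if weights.sum() <= 0 and n_internal > 0:
        raise ConnectomeError("blueprint weights are all zero for this area")
    return allocate_integers(n_internal, weights.ravel()).reshape(weights.shape)


def distribute_external_drive(
    blueprint: LocalBlueprint,
    area_sizes: np.ndarray,
    n_external: int,
) -> np.ndarray:
    """Distribute external-drive synapses over target populations.

    Proportional to k_ext_pd[target] * N_target: the blueprint fixes the
    relative, not absolute, external indegrees.
    """
    sizes = np.asarray(area_sizes, dtype=float)
    weights = blueprint.k_ext_pd * sizes
    if weights.sum() <= 0 and n_external > 0:
        raise ConnectomeError("external-drive weights are all zero for this area")
    return allocate_integers(n_external, weights)


def allocate_longrange_sources(
    tracts,
    target_index: int,
    n_nonlocal: int,
    area_names: list[str] | None = None,
) -> np.ndarray:
    """Distribute non-local synapses over source areas by relative NoS.

    Self-connections are excluded; an isolated target area (all-zero NoS
    column) with a nonzero budget is an error.
    """
    nos_to_target = np.asarray(tracts.nos[:, target_index], dtype=float).copy()
    nos_to_target[target_index] = 0.0
    if nos_to_target.sum() <= 0 and n_nonlocal > 0:
        name = area_names[target_index] if area_names else str(target_index)
        raise ConnectomeError(
            f"area {name!r} has no incoming streamlines but a nonzero "
            f"long-range synapse budget"
        )
    return allocate_integers(n_nonlocal, nos_to_target)


# ---------------------------------------------------------------------------
# laminar patterns
# ---------------------------------------------------------------------------

def predict_sln(rho_target: float, rho_source: float, fit: SLNFitParams) -> float:
    """Predicted fraction of supragranular labeled neurons of a projection.

    SLN(B->A) = Phi(a0 + a1 * ln(rho_A / rho_B)) with Phi the standard normal
    CDF and rho the area-level neuron densities; denser (typically earlier)
    areas project mostly from layer 2/3 onto sparser ones.
    """
    if rho_target <= 0 or rho_source <= 0:
        raise ConnectomeError("neuron densities must be positive")
    return float(norm.cdf(fit.a0 + fit.a1 * np.log(rho_target / rho_source)))


def sln_matrix(bundle: AnatomyBundle) -> np.ndarray:
    """SLN for every ordered (source, target) area pair; diagonal NaN."""
    rho = np.array([a.mean_density(bundle.constants.column_area) for a in bundle.areas])
    n = len(rho)
    out = np.full((n, n), np.nan)
    for s in range(n):
        for t in range(n):
            if s != t:
                out[s, t] = predict_sln(rho[t], rho[s], bundle.sln_fit)
    return out


def laminar_source_counts(
    sln: float,
    source_sizes: np.ndarray,
    n_syn: int,
) -> np.ndarray:
    """Distribute a projection's synapses over source populations.

    A fraction SLN originates from layer 2/3 excitatory neurons; the rest is
    split between 5E and 6E in proportion to their sizes. Layer 4 does not
    form long-range projections and inhibitory neurons never project between
    areas. A supragranular share with no 2/3E population (or infragranular
    share with no 5E/6E) is reassigned to the remaining eligible populations.
    """
    if not 0 <= sln <= 1:
        raise ConnectomeError(f"sln must be in [0, 1], got {sln}")
    sizes = np.asarray(source_sizes, dtype=float)
    weights = np.zeros(len(POPULATION_LABELS))
    i23e = POPULATION_LABELS.index("2/3E")
    i5e = POPULATION_LABELS.index("5E")
    i6e = POPULATION_LABELS.index("6E")
    if sizes[i23e] > 0:
        weights[i23e] = sln
    n_infra = sizes[i5e] + sizes[i6e]
    if n_infra > 0:
        weights[i5e] = (1.0 - sln) * sizes[i5e] / n_infra
        weights[i6e] = (1.0 - sln) * sizes[i6e] / n_infra
    if weights.sum() <= 0:
        if n_syn == 0:
            return np.zeros(len(POPULATION_LABELS), dtype=np.int64)
        raise ConnectomeError("source area has no eligible projecting population")
    return allocate_integers(n_syn, weights)


def laminar_target_distribution(
    sln: float,
    synapse_layer_thickness: dict[str, float],
    agranular: bool,
    ff_threshold: float = 0.65,
    fb_threshold: float = 0.35,
) -> np.ndarray:
    """Weights over synapse layers {1, 2/3, 4, 5, 6} for a projection.

    Feedforward projections (SLN > ff_threshold) terminate in layer 4 (layer
    2/3 for agranular targets); lateral projections spread over all layers
    and feedback projections (SLN < fb_threshold) avoid layer 4, in both
    cases weighted by the relative thickness of the pattern's layers.
    """
    weights = np.zeros(len(SYNAPSE_LAYERS))
    if sln > ff_threshold:
        layer = "2/3" if agranular else "4"
        weights[SYNAPSE_LAYERS.index(layer)] = 1.0
        return weights
    pattern = list(SYNAPSE_LAYERS) if sln >= fb_threshold else ["1", "2/3", "5", "6"]
    for layer in pattern:
        weights[SYNAPSE_LAYERS.index(layer)] = synapse_layer_thickness.get(layer, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ConnectomeError("target pattern layers have zero total thickness")
    return weights / total


def resolve_postsynaptic_targets(
    layer_weights: np.ndarray,
    ei_exc_prob: dict[str, float],
    dendrites: DendriticProfile,
    sln: float,
    constants: ModelConstants,
    target_sizes: np.ndarray | None = None,
) -> np.ndarray:
    """Turn synapse-layer weights into weights over target populations.

    Excitatory targets: the synapse-layer weight times the per-layer
    excitatory probability is routed to soma layers through the dendritic-
    length profile and the synapse location marginalized out. Inhibitory
    targets sit in the synapse's own layer; the layer-1 inhibitory share
    (layer 1 has no neurons) is reassigned proportionally to the other
    layers' inhibitory shares. Feedback projections (SLN < fb threshold)
    have their total excitatory share fixed at ``fb_exc_target_fraction``.
    Weights of absent populations are dropped and the rest renormalized.
    """
    layer_weights = np.asarray(layer_weights, dtype=float)
    if layer_weights.shape != (len(SYNAPSE_LAYERS),):
        raise ConnectomeError("layer_weights must cover the five synapse layers")
    exc = np.zeros(len(LAYERS))  # per soma layer
    inh = np.zeros(len(LAYERS))  # per synapse layer (= soma layer)
    l1_inh = 0.0
    for i, syn_layer in enumerate(SYNAPSE_LAYERS):
        w = layer_weights[i]
        if w == 0:
            continue
        p_e = ei_exc_prob[syn_layer]
        exc += w * p_e * dendrites.soma_probabilities(syn_layer)
        if syn_layer == "1":
            l1_inh += w * (1.0 - p_e)
        else:
            inh[LAYERS.index(syn_layer)] += w * (1.0 - p_e)
    if l1_inh > 0:
        if inh.sum() > 0:
            inh += l1_inh * inh / inh.sum()
        else:
            # no inhibitory share anywhere else: give layer 1's to excitatory
            exc += l1_inh * exc / exc.sum()

    if sln < constants.sln_fb_threshold:
        # feedback: excitatory target share fixed
        fe = constants.fb_exc_target_fraction
        if exc.sum() > 0:
            exc *= fe / exc.sum()
        if inh.sum() > 0:
            inh *= (1.0 - fe) / inh.sum()
        else:
            exc *= 1.0 / fe  # no inhibitory candidates: everything excitatory

    out = np.zeros(len(POPULATION_LABELS))
    for j, layer in enumerate(LAYERS):
        out[2 * j] = exc[j]
        out[2 * j + 1] = inh[j]
    if target_sizes is not None:
        sizes = np.asarray(target_sizes, dtype=float)
        out = np.where(sizes > 0, out, 0.0)
    total = out.sum()
    if total <= 0:
        raise ConnectomeError(
            "no existing postsynaptic population can absorb this projection"
        )
    return out / total


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

def assemble_connectome(
    bundle: AnatomyBundle,
    quad_rel_tol: float = 1e-3,
) -> tuple[PopulationGrid, SynapseCounts]:
    """Run the full construction for every area and area pair.

    Returns the population grid and the synapse-count matrix; every
    allocation stage conserves its parent budget exactly, which is recorded
    per area in ``SynapseCounts.bookkeeping``.
    """
    grid = compute_population_sizes(bundle)
    n_pop = grid.n_populations
    n_per_area = len(POPULATION_LABELS)
    internal = np.zeros((n_pop, n_pop), dtype=np.int64)
    external = np.zeros(n_pop, dtype=np.int64)
    bookkeeping: dict[str, dict[str, int]] = {}

    f_nl = nonlocal_fraction(bundle.constants)
    slns = sln_matrix(bundle)

    for t_idx, area in enumerate(bundle.areas):
        t_slice = grid.area_slice(area.name)
        t_sizes = grid.area_sizes(area.name)
        n_total = compute_area_synapse_budget(bundle, area)
        rho_i, rho_e = column_density_integrals(
            h=area.total_thickness + area.l1_thickness,
            area_surface=area.surface_area,
            lambda_conn=bundle.constants.lambda_conn,
            column_area=bundle.constants.column_area,
            rel_tol=quad_rel_tol,
        )
        n_int, n_ext, n_nonlocal = split_synapse_budget(n_total, f_nl, rho_i, rho_e)

        internal[t_slice, t_slice] = distribute_internal(
            bundle.blueprint, t_sizes, n_int
        )
        external[t_slice] = distribute_external_drive(bundle.blueprint, t_sizes, n_ext)

        per_source = allocate_longrange_sources(
            bundle.tracts, t_idx, n_nonlocal, grid.area_names
        )
        thickness = area.synapse_layer_thickness()
        for s_idx, n_syn in enumerate(per_source):
            if n_syn == 0:
                continue
            source = bundle.areas[s_idx]
            sln = slns[s_idx, t_idx]
            s_sizes = grid.area_sizes(source.name)
            src_weights = laminar_source_counts(sln, s_sizes, int(n_syn)).astype(float)
            layer_w = laminar_target_distribution(
                sln,
                thickness,
                agranular=area.is_agranular,
                ff_threshold=bundle.constants.sln_ff_threshold,
                fb_threshold=bundle.constants.sln_fb_threshold,
            )
            tgt_weights = resolve_postsynaptic_targets(
                layer_w,
                bundle.ei_target_exc_prob,
                bundle.dendrites,
                sln,
                bundle.constants,
                target_sizes=t_sizes,
            )
            joint = tgt_weights[:, None] * src_weights[None, :]
            block = allocate_integers(int(n_syn), joint.ravel()).reshape(
                n_per_area, n_per_area
            )
            s_slice = grid.area_slice(source.name)
            internal[t_slice, s_slice] += block

        bookkeeping[area.name] = {
            "N_total": int(n_total),
            "N_local": int(n_int + n_ext),
            "N_nonlocal": int(n_nonlocal),
            "N_internal": int(n_int),
            "N_external": int(n_ext),
        }

    # conservation sanity: absent populations must be silent
    absent = ~grid.exists
    if internal[absent, :].sum() or internal[:, absent].sum() or external[absent].sum():
        raise ConnectomeError("absent populations received or sent synapses")

    return grid, SynapseCounts(
        internal=internal, external_drive=external, bookkeeping=bookkeeping
    )
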