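"""Anatomical inputs of the mesoconnectome builder.

The builder consumes, for every cortical area, layer thicknesses, neuron volume
densities, surface areas and excitatory fractions, together with an inter-areal
streamline-count matrix (NoS) and fiber-length matrix from diffusion
tractography, a local-circuit blueprint (relative synapse numbers per neuron
pair and reference external indegrees of a layered microcircuit), a
layer-resolved dendritic-length matrix from morphological reconstructions, and
the parameters of the probit fit that predicts the laminar origin of
long-range projections (SLN) from relative neuron densities.

All tabular inputs are plain CSV; :func:`load_anatomy_bundle` and
:func:`write_bundle` round-trip them exactly.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .areas import LAYERS, POPULATION_LABELS, SYNAPSE_LAYERS

__all__ = [
    "AreaAnatomy",
    "TractData",
    "LocalBlueprint",
    "DendriticProfile",
    "SLNFitParams",
    "ModelConstants",
    "AnatomyBundle",
    "AnatomyError",
    "load_anatomy_bundle",
    "write_bundle",
    "aggregate_vek_to_dk",
    "DEFAULT_EXC_FRACTION",
    "DEFAULT_EI_TARGET_EXC_PROB",
]


class AnatomyError(ValueError):
    """Raised when anatomical inputs fail validation."""


#: Fraction of excitatory neurons per layer (electron-microscopy estimate,
#: human temporal lobe); used wherever an input table omits the column.
DEFAULT_EXC_FRACTION: dict[str, float] = {"2/3": 0.65, "4": 0.79, "5": 0.78, "6": 0.86}

#: Probability that a long-range synapse in a given layer contacts an
#: excitatory (rather than inhibitory) postsynaptic neuron. The model uses a
#: single cortex-wide value per synapse layer. The shipped default is a
#: placeholder aggregate (configurable via ``ei_target_exc_prob``); for
#: feedback projections it is overridden by the fixed 93% excitatory share.
DEFAULT_EI_TARGET_EXC_PROB: dict[str, float] = {
    "1": 0.90, "2/3": 0.80, "4": 0.80, "5": 0.82, "6": 0.84,
}


@dataclasses.dataclass
class AreaAnatomy:
    """Per-area cytoarchitecture: geometry, densities and E/I composition.

    Layer 1 contains no modeled neurons (its neuron density is negligible)
    but it does receive long-range synapses, so its thickness enters the
    laminar target patterns; it is carried separately as ``l1_thickness``.
    """

    name: str
    surface_area: float  # mm^2
    layer_thickness: dict[str, float]  # layer -> mm; 0 marks an absent layer
    neuron_density: dict[str, float]  # layer -> neurons/mm^3
    excitatory_fraction: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EXC_FRACTION)
    )
    l1_thickness: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.surface_area <= 0:
            raise AnatomyError(f"area {self.name!r}: surface_area must be > 0")
        if self.l1_thickness < 0:
            raise AnatomyError(f"area {self.name!r}: negative layer-1 thickness")
        for layer in LAYERS:
            if layer not in self.layer_thickness:
                raise AnatomyError(f"area {self.name!r}: missing thickness for layer {layer}")
            if layer not in self.neuron_density:
                raise AnatomyError(f"area {self.name!r}: missing density for layer {layer}")
            if self.layer_thickness[layer] < 0:
                raise AnatomyError(
                    f"area {self.name!r}, layer {layer}: negative thickness "
                    f"{self.layer_thickness[layer]}"
                )
            if self.neuron_density[layer] < 0:
                raise AnatomyError(
                    f"area {self.name!r}, layer {layer}: negative density "
                    f"{self.neuron_density[layer]}"
                )
            f = self.excitatory_fraction.setdefault(layer, DEFAULT_EXC_FRACTION[layer])
            if not 0.0 <= f <= 1.0:
                raise AnatomyError(
                    f"area {self.name!r}, layer {layer}: excitatory fraction {f} not in [0, 1]"
                )

    @property
    def total_thickness(self) -> float:
        """Summed thickness of the neuron-bearing layers (mm), excluding layer 1."""
        return sum(self.layer_thickness[layer] for layer in LAYERS)

    def synapse_layer_thickness(self) -> dict[str, float]:
        """Thickness per synapse layer {1, 2/3, 4, 5, 6} (mm)."""
        out = {"1": self.l1_thickness}
        out.update({layer: self.layer_thickness[layer] for layer in LAYERS})
        return out

    @property
    def is_agranular(self) -> bool:
        """True if the area lacks a (functional) layer 4."""
        return self.layer_thickness["4"] == 0.0

    def mean_density(self, column_area: float = 1.0) -> float:
        """Area-level neuron density: total neurons / total volume (per mm^3)."""
        h = self.total_thickness
        if h <= 0:
            raise AnatomyError(f"area {self.name!r}: zero total thickness")
        n = sum(
            self.neuron_density[layer] * self.layer_thickness[layer] * column_area
            for layer in LAYERS
        )
        return n / (h * column_area)


@dataclasses.dataclass
class TractData:
    """Inter-areal streamline counts and fiber lengths (DTI-derived)."""

    nos: np.ndarray  # (n_areas, n_areas), NoS[source, target]; diagonal ignored
    fiber_length: np.ndarray  # (n_areas, n_areas), mm; symmetric

    def __post_init__(self) -> None:
        self.nos = np.asarray(self.nos, dtype=float)
        self.fiber_length = np.asarray(self.fiber_length, dtype=float)
        if self.nos.ndim != 2 or self.nos.shape[0] != self.nos.shape[1]:
            raise AnatomyError(f"nos matrix must be square, got shape {self.nos.shape}")
        if self.fiber_length.shape != self.nos.shape:
            raise AnatomyError(
                f"fiber_length shape {self.fiber_length.shape} does not match "
                f"nos shape {self.nos.shape}"
            )
        if np.any(self.nos < 0):
            raise AnatomyError("nos matrix contains negative entries")
        off = ~np.eye(self.nos.shape[0], dtype=bool)
        if np.any(self.fiber_length[off] <= 0):
            raise AnatomyError("fiber_length must be positive off-diagonal")
        if not np.allclose(self.fiber_length, self.fiber_length.T):
            raise AnatomyError("fiber_length matrix must be symmetric")

    @property
    def n_areas(self) -> int:
        return self.nos.shape[0]


# Local-circuit blueprint defaults: connection probabilities and reference
# external indegrees of the standard 4-layer, 8-population microcircuit model
# (rows: target population, columns: source population, order 2/3E ... 6I).
# Only the *relative* synapse numbers per neuron pair matter downstream; they
# are obtained as -ln(1 - p), the expected synapse count per pair under the
# fixed-total-number rule up to a common factor.
_PD_CONNECTION_PROB = np.array([
    #   2/3E    2/3I    4E      4I      5E      5I      6E      6I
    [0.1009, 0.1689, 0.0437, 0.0818, 0.0323, 0.0000, 0.0076, 0.0000],  # -> 2/3E
    [0.1346, 0.1371, 0.0316, 0.0515, 0.0755, 0.0000, 0.0042, 0.0000],  # -> 2/3I
    [0.0077, 0.0059, 0.0497, 0.1350, 0.0067, 0.0003, 0.0453, 0.0000],  # -> 4E
    [0.0691, 0.0029, 0.0794, 0.1597, 0.0033, 0.0000, 0.1057, 0.0000],  # -> 4I
    [0.1004, 0.0622, 0.0505, 0.0057, 0.0831, 0.3726, 0.0204, 0.0000],  # -> 5E
    [0.0548, 0.0269, 0.0257, 0.0022, 0.0600, 0.3158, 0.0086, 0.0000],  # -> 5I
    [0.0156, 0.0066, 0.0211, 0.0166, 0.0572, 0.0197, 0.0396, 0.2252],  # -> 6E
    [0.0364, 0.0010, 0.0034, 0.0005, 0.0277, 0.0080, 0.0658, 0.1443],  # -> 6I
])

_PD_K_EXT = np.array([1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100], dtype=float)


@dataclasses.dataclass
class LocalBlueprint:
    """Relative local-circuit connectivity of a layered microcircuit.

    ``q_pd[target, source]`` is the average number of synapses per neuron pair
    (arbitrary common scale; only ratios matter), ``k_ext_pd`` the reference
    external indegree per target population. Population order follows
    :data:`mesocortex.areas.POPULATION_LABELS`. The doubling of 4E->2/3E
    synaptic *weights* is a simulator rule, not part of this matrix.
    """

    q_pd: np.ndarray
    k_ext_pd: np.ndarray

    def __post_init__(self) -> None:
        self.q_pd = np.asarray(self.q_pd, dtype=float)
        self.k_ext_pd = np.asarray(self.k_ext_pd, dtype=float)
        n = len(POPULATION_LABELS)
        if self.q_pd.shape != (n, n):
            raise AnatomyError(f"blueprint q matrix must be {n}x{n}, got {self.q_pd.shape}")
        if self.k_ext_pd.shape != (n,):
            raise AnatomyError(f"k_ext vector must have length {n}, got {self.k_ext_pd.shape}")
        if np.any(self.q_pd < 0) or np.any(self.k_ext_pd < 0):
            raise AnatomyError("blueprint entries must be nonnegative")

    @classmethod
    def default(cls) -> "LocalBlueprint":
        return cls(q_pd=-np.log1p(-_PD_CONNECTION_PROB), k_ext_pd=_PD_K_EXT.copy())


# Synthetic default dendritic-length matrix (rows: synapse layer 1..6, columns:
# soma layer 2/3..6). Mimics pyramidal morphology: basal dendrites concentrated
# in the soma layer, apical tufts reaching layer 1. Placeholder values, not
# measured data; real reconstructions are supplied via dendrites.csv.
_DEFAULT_DENDRITE_LENGTHS = np.array([
    #  2/3    4     5     6     (soma layer)
    [0.50, 0.20, 0.25, 0.05],  # synapse in layer 1
    [0.80, 0.15, 0.20, 0.05],  # synapse in layer 2/3
    [0.10, 0.70, 0.15, 0.05],  # synapse in layer 4
    [0.05, 0.10, 0.70, 0.15],  # synapse in layer 5
    [0.02, 0.05, 0.15, 0.80],  # synapse in layer 6
])


@dataclasses.dataclass
class DendriticProfile:
    """Layer-resolved dendritic length ``ell[synapse_layer, soma_layer]``.

    Normalized row-wise it gives P(soma in B | synapse in A), the probability
    that a synapse located in layer A sits on the dendrite of an excitatory
    neuron whose soma is in layer B (constant synapse density along dendrites).
    """

    ell: np.ndarray

    def __post_init__(self) -> None:
        self.ell = np.asarray(self.ell, dtype=float)
        shape = (len(SYNAPSE_LAYERS), len(LAYERS))
        if self.ell.shape != shape:
            raise AnatomyError(f"dendrite matrix must be {shape}, got {self.ell.shape}")
        if np.any(self.ell < 0):
            raise AnatomyError("dendritic lengths must be nonnegative")

    @classmethod
    def default(cls) -> "DendriticProfile":
        return cls(ell=_DEFAULT_DENDRITE_LENGTHS.copy())

    def soma_probabilities(self, synapse_layer: str) -> np.ndarray:
        """P(soma layer | synapse layer) over the four soma layers."""
        row = self.ell[SYNAPSE_LAYERS.index(synapse_layer)]
        total = row.sum()
        if total <= 0:
            raise AnatomyError(
                f"dendrite row for synapse layer {synapse_layer!r} sums to zero"
            )
        return row / total


@dataclasses.dataclass
class SLNFitParams:
    """Probit-fit parameters relating density ratios to laminar origin (SLN)."""

    a0: float = -0.152
    a1: float = -1.534

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a0) and math.isfinite(self.a1)):
            raise AnatomyError("SLN fit parameters must be finite")


@dataclasses.dataclass
class ModelConstants:
    """Global constants of the connectome construction.

    rho_synapse
        Volume density of synapses (synapses/mm^3), constant across cortex.
    lambda_conn
        Decay constant of the local exponential connection probability (mm).
    column_area
        Modeled cortical patch per area (mm^2).
    calib_fraction, calib_neurons, human_neurons, scaling_exponent
        Calibration of the white-matter scaling rule: a fraction
        ``calib_fraction`` of neurons send axons into the white matter at
        ``calib_neurons`` gray-matter neurons, and this fraction scales with
        total neuron number to the power ``-scaling_exponent``.
    sln_ff_threshold, sln_fb_threshold
        SLN cut-offs for feedforward (>) and feedback (<) classification.
    fb_exc_target_fraction
        Fixed excitatory share of postsynaptic targets of feedback projections.
    """

    rho_synapse: float = 6.6e8
    lambda_conn: float = 0.160
    column_area: float = 1.0
    calib_fraction: float = 0.21
    calib_neurons: float = 1.4e9
    human_neurons: float = 16e9
    scaling_exponent: float = 0.16
    sln_ff_threshold: float = 0.65
    sln_fb_threshold: float = 0.35
    fb_exc_target_fraction: float = 0.93

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if getattr(self, field.name) <= 0:
                raise AnatomyError(f"constant {field.name} must be positive")
        if not self.sln_fb_threshold < self.sln_ff_threshold:
            raise AnatomyError("sln thresholds must satisfy fb < ff")


@dataclasses.dataclass
class AnatomyBundle:
    """All anatomical inputs of the connectome builder, with consistent area order."""

    areas: list[AreaAnatomy]
    tracts: TractData
    blueprint: LocalBlueprint
    dendrites: DendriticProfile
    sln_fit: SLNFitParams = dataclasses.field(default_factory=SLNFitParams)
    constants: ModelConstants = dataclasses.field(default_factory=ModelConstants)
    ei_target_exc_prob: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EI_TARGET_EXC_PROB)
    )

    def __post_init__(self) -> None:
        if len(self.areas) != self.tracts.n_areas:
            raise AnatomyError(
                f"{len(self.areas)} areas but tract matrices are "
                f"{self.tracts.n_areas}x{self.tracts.n_areas}"
            )
        names = [a.name for a in self.areas]
        if len(set(names)) != len(names):
            raise AnatomyError("duplicate area names")
        for layer in SYNAPSE_LAYERS:
            if layer not in self.ei_target_exc_prob:
                raise AnatomyError(f"ei_target_exc_prob missing layer {layer}")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def area_names(self) -> list[str]:
        return [a.name for a in self.areas]

    def area_index(self, name: str) -> int:
        try:
            return self.area_names.index(name)
        except ValueError:
            raise AnatomyError(f"unknown area {name!r}") from None


# ---------------------------------------------------------------------------
# von Economo-Koskinas -> Desikan-Killiany aggregation
# ---------------------------------------------------------------------------

def aggregate_vek_to_dk(
    sub_areas: list[tuple[dict[str, float], dict[str, float]]],
) -> tuple[dict[str, float], dict[str, float]]:
    """Aggregate cytoarchitectonic sub-areas into one target-parcellation area.

    Each element of ``sub_areas`` is a ``(thicknesses, densities)`` pair over
    the modeled layers, with sub-layer thicknesses already summed per layer.
    The aggregated thickness is the unweighted mean across sub-areas; the
    aggregated density weights each sub-area by its relative layer thickness
    (so thicker cortices contribute proportionally more neurons).
    """
    if not sub_areas:
        raise AnatomyError("aggregate_vek_to_dk requires at least one sub-area")
    thickness: dict[str, float] = {}
    density: dict[str, float] = {}
    for layer in LAYERS:
        hs = np.array([h.get(layer, 0.0) for h, _ in sub_areas], dtype=float)
        ds = np.array([d.get(layer, 0.0) for _, d in sub_areas], dtype=float)
        if np.any(hs < 0) or np.any(ds < 0):
            raise AnatomyError(f"layer {layer}: negative thickness or density")
        thickness[layer] = float(hs.mean())
        total_h = hs.sum()
        if total_h > 0:
            density[layer] = float((hs * ds).sum() / total_h)
        else:
            if np.any(ds > 0):
                raise AnatomyError(
                    f"layer {layer}: zero total thickness but nonzero density"
                )
            density[layer] = 0.0
    return thickness, density


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_AREA_COLUMNS = ["area", "layer", "thickness_mm", "density_per_mm3", "exc_fraction", "surface_mm2"]


def _read_matrix_csv(path: Path, expected_names: list[str], what: str) -> np.ndarray:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    names = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != names:
        raise AnatomyError(f"{what}: row and column headers differ in {path}")
    if names != expected_names:
        if set(names) != set(expected_names):
            missing = set(expected_names) - set(names)
            extra = set(names) - set(expected_names)
            raise AnatomyError(
                f"{what}: area names do not match areas.csv "
                f"(missing {sorted(missing)}, unknown {sorted(extra)}) in {path}"
            )
        df = df.loc[expected_names, expected_names]
    m = df.to_numpy(dtype=float)
    if m.shape != (len(expected_names), len(expected_names)):
        raise AnatomyError(
            f"{what}: expected {len(expected_names)}x{len(expected_names)} matrix, "
            f"got {m.shape} in {path}"
        )
    return m


def load_anatomy_bundle(
    paths: dict[str, str | Path],
    constants_override: dict[str, float] | None = None,
) -> AnatomyBundle:
    """Load and validate an :class:`AnatomyBundle` from CSV files.

    ``paths`` maps the keys ``areas``, ``nos``, ``fiber_length`` (required) and
    ``blueprint``, ``k_ext``, ``dendrites`` (optional; built-in defaults are
    used when absent) to file paths. ``constants_override`` overrides
    individual :class:`ModelConstants` fields.
    """
    for key in ("areas", "nos", "fiber_length"):
        if key not in paths:
            raise AnatomyError(f"missing required input file for {key!r}")

    df = pd.read_csv(paths["areas"], float_precision="round_trip")
    missing_cols = {"area", "layer", "thickness_mm", "density_per_mm3", "surface_mm2"} - set(df.columns)
    if missing_cols:
        raise AnatomyError(f"areas.csv missing columns {sorted(missing_cols)}")
    areas: list[AreaAnatomy] = []
    for name, group in df.groupby("area", sort=False):
        thickness: dict[str, float] = {}
        density: dict[str, float] = {}
        exc: dict[str, float] = {}
        l1 = 0.0
        for _, row in group.iterrows():
            layer = str(row["layer"])
            if layer == "1":
                l1 = float(row["thickness_mm"])
                continue
            if layer not in LAYERS:
                raise AnatomyError(f"area {name!r}: unknown layer {layer!r}")
            thickness[layer] = float(row["thickness_mm"])
            density[layer] = float(row["density_per_mm3"])
            if "exc_fraction" in group.columns and not pd.isna(row.get("exc_fraction")):
                exc[layer] = float(row["exc_fraction"])
        for layer in LAYERS:
            exc.setdefault(layer, DEFAULT_EXC_FRACTION[layer])
        areas.append(
            AreaAnatomy(
                name=str(name),
                surface_area=float(group["surface_mm2"].iloc[0]),
                layer_thickness=thickness,
                neuron_density=density,
                excitatory_fraction=exc,
                l1_thickness=l1,
            )
        )
    names = [a.name for a in areas]

    nos = _read_matrix_csv(Path(paths["nos"]), names, "nos")
    fiber = _read_matrix_csv(Path(paths["fiber_length"]), names, "fiber_length")
    tracts = TractData(nos=nos, fiber_length=fiber)

    if "blueprint" in paths:
        bdf = pd.read_csv(paths["blueprint"], index_col=0, float_precision="round_trip")
        q = bdf.to_numpy(dtype=float)
        kdf = pd.read_csv(paths["k_ext"], index_col=0, float_precision="round_trip") if "k_ext" in paths else None
        k = (
            kdf.to_numpy(dtype=float).ravel()
            if kdf is not None
            else LocalBlueprint.default().k_ext_pd
        )
        blueprint = LocalBlueprint(q_pd=q, k_ext_pd=k)
    else:
        blueprint = LocalBlueprint.default()

    if "dendrites" in paths:
        ddf = pd.read_csv(paths["dendrites"], index_col=0, float_precision="round_trip")
        dendrites = DendriticProfile(ell=ddf.to_numpy(dtype=float))
    else:
        dendrites = DendriticProfile.default()

    constants = ModelConstants(**(constants_override or {}))
    return AnatomyBundle(
        areas=areas, tracts=tracts, blueprint=blueprint, dendrites=dendrites,
        constants=constants,
    )


def write_bundle(bundle: AnatomyBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle to CSV files in ``directory``; inverse of the loader."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for area in bundle.areas:
        rows.append({
            "area": area.name,
            "layer": "1",
            "thickness_mm": area.l1_thickness,
            "density_per_mm3": 0.0,
            "exc_fraction": 0.0,
            "surface_mm2": area.surface_area,
        })
        for layer in LAYERS:
            rows.append({
                "area": area.name,
                "layer": layer,
                "thickness_mm": area.layer_thickness[layer],
                "density_per_mm3": area.neuron_density[layer],
                "exc_fraction": area.excitatory_fraction[layer],
                "surface_mm2": area.surface_area,
            })
    paths = {
        "areas": directory / "areas.csv",
        "nos": directory / "nos.csv",
        "fiber_length": directory / "fiber_length_mm.csv",
        "blueprint": directory / "blueprint.csv",
        "k_ext": directory / "k_ext.csv",
        "dendrites": directory / "dendrites.csv",
    }
    pd.DataFrame(rows, columns=_AREA_COLUMNS).to_csv(paths["areas"], index=False, float_format="%.17g")
    names = bundle.area_names
    pd.DataFrame(bundle.tracts.nos, index=names, columns=names).to_csv(paths["nos"], float_format="%.17g")
    pd.DataFrame(bundle.tracts.fiber_length, index=names, columns=names).to_csv(
        paths["fiber_length"], float_format="%.17g"
    )
    labels = list(POPULATION_LABELS)
    pd.DataFrame(bundle.blueprint.q_pd, index=labels, columns=labels).to_csv(
        paths["blueprint"], float_format="%.17g"
    )
    pd.DataFrame({"k_ext": bundle.blueprint.k_ext_pd}, index=labels).to_csv(paths["k_ext"], float_format="%.17g")
    pd.DataFrame(
        bundle.dendrites.ell, index=list(SYNAPSE_LAYERS), columns=list(LAYERS)
    ).to_csv(paths["dendrites"], float_format="%.17g")
    return paths
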