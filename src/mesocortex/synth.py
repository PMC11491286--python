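"""Synthetic anatomy generator.

Emulates the statistical structure of the real anatomical inputs so the whole
pipeline is testable without downloads: streamline counts are log-normal with
an exponential decay over inter-areal distance (the two salient features of
tract-tracing and tractography data), distances come from random points on a
sphere of brain scale, and cytoarchitecture (layer thicknesses, neuron
densities, surface areas) is drawn uniformly within plausible human cortical
ranges. With the default 34 areas the resulting model has a few million
neurons, matching the scale of the real single-hemisphere model.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .anatomy import (
    AnatomyBundle,
    AnatomyError,
    AreaAnatomy,
    DendriticProfile,
    LocalBlueprint,
    ModelConstants,
    SLNFitParams,
    TractData,
)
from .areas import DK_NAMES, LAYERS

__all__ = ["SynthSpec", "synth_anatomy"]


@dataclasses.dataclass
class SynthSpec:
    """Distribution parameters of the synthetic anatomy.

    nos_mu, nos_sigma
        Mean and SD of ln(NoS) before the distance decay is applied.
    lambda_spec
        Exponential decay constant of NoS with distance (mm).
    sphere_radius
        Radius of the sphere on which area centers are placed (mm);
        60 mm yields inter-areal distances on the scale of human fiber lengths.
    thickness_range, density_range, surface_range
        Uniform ranges per layer (mm), for volume density (neurons/mm^3) and
        for area surface (mm^2).
    """

    nos_mu: float = 7.0
    nos_sigma: float = 1.0
    lambda_spec: float = 45.0
    sphere_radius: float = 60.0
    thickness_range: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {
            "1": (0.1, 0.3),
            "2/3": (0.5, 1.1), "4": (0.1, 0.4), "5": (0.3, 0.7), "6": (0.3, 0.8),
        }
    )
    density_range: tuple[float, float] = (25e3, 75e3)
    surface_range: tuple[float, float] = (400.0, 2500.0)

    def __post_init__(self) -> None:
        if self.nos_sigma < 0:
            raise AnatomyError(f"nos_sigma must be >= 0, got {self.nos_sigma}")
        if self.lambda_spec <= 0 or self.sphere_radius <= 0:
            raise AnatomyError("lambda_spec and sphere_radius must be positive")
        for layer, (lo, hi) in self.thickness_range.items():
            if lo < 0 or hi < lo:
                raise AnatomyError(f"invalid thickness range for layer {layer}")


def synth_anatomy(
    seed: int,
    n_areas: int = 34,
    spec: SynthSpec | None = None,
) -> tuple[AnatomyBundle, SynthSpec]:
    """Generate a reproducible synthetic :class:`AnatomyBundle`.

    Returns the bundle together with the generating parameters, so that
    parameter-recovery checks (log-normal fit of NoS, distance-decay fit)
    can compare against ground truth.
    """
    if n_areas < 2:
        raise AnatomyError(f"n_areas must be >= 2, got {n_areas}")
    spec = spec or SynthSpec()
    rng = np.random.default_rng(seed)

    names = list(DK_NAMES[:n_areas])
    names += [f"synth{i}" for i in range(len(names), n_areas)]

    # Area centers uniform on a sphere surface; distances are Euclidean chords.
    points = rng.normal(size=(n_areas, 3))
    points *= spec.sphere_radius / np.linalg.norm(points, axis=1, keepdims=True)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, 0.0)

    # Symmetric log-normal NoS modulated by exponential distance decay
    # (streamline counts are undirected).
    log_nos = rng.normal(spec.nos_mu, spec.nos_sigma, size=(n_areas, n_areas))
    log_nos = np.triu(log_nos, k=1)
    log_nos = log_nos + log_nos.T
    nos = np.exp(log_nos) * np.exp(-dist / spec.lambda_spec)
    np.fill_diagonal(nos, 0.0)

    fiber = dist.copy()
    # keep fiber_length positive off-diagonal even for coincident draws
    off = ~np.eye(n_areas, dtype=bool)
    fiber[off] = np.maximum(fiber[off], 1e-3)

    areas = []
    for i, name in enumerate(names):
        thickness = {
            layer: float(rng.uniform(*spec.thickness_range[layer])) for layer in LAYERS
        }
        density = {
            layer: float(rng.uniform(*spec.density_range)) for layer in LAYERS
        }
        areas.append(
            AreaAnatomy(
                name=name,
                surface_area=float(rng.uniform(*spec.surface_range)),
                layer_thickness=thickness,
                neuron_density=density,
                l1_thickness=float(rng.uniform(*spec.thickness_range["1"])),
            )
        )

    bundle = AnatomyBundle(
        areas=areas,
        tracts=TractData(nos=nos, fiber_length=fiber),
        blueprint=LocalBlueprint.default(),
        dendrites=DendriticProfile.default(),
        sln_fit=SLNFitParams(),
        constants=ModelConstants(),
    )
    return bundle, spec
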