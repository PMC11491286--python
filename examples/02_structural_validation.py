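"""Validate an assembled connectome against hallmark structural features.

Checks features that are not built in directly: the spread and log-normal
shape of pairwise synapse counts, the exponential decay of inter-areal
connectivity with fiber distance, the feedforward/feedback outdegree
asymmetry, and the small-world path statistics of the population graph.
"""

from mesocortex import assemble_connectome, sln_matrix, synth_anatomy, validate_connectome
from mesocortex.params import DelayParams

bundle, spec = synth_anatomy(seed=1, n_areas=34)
grid, counts = assemble_connectome(bundle)
report = validate_connectome(
    counts, grid, bundle.tracts, sln_matrix(bundle), DelayParams()
)

print(f"log10 synapse counts: mean {report.lognormal_mu:.2f}, "
      f"sd {report.lognormal_sigma:.2f}")
print(f"distance decay constant: {report.decay_constant_mm:.1f} mm "
      f"(generator used {spec.lambda_spec:.1f} mm)")
print(f"mean outdegree by direction: " +
      ", ".join(f"{k}={v:.0f}" for k, v in report.outdegree_mean.items()))
print(f"mean #target areas (outdegree>100): " +
      ", ".join(f"{k}={v:.2f}" for k, v in report.target_area_mean.items()))
print(f"max shortest path (hops): {report.path_length_max}")
print(f"max delay-weighted path:  {report.delay_path_max_ms:.1f} ms")

# A decay constant close to the generating value shows the allocation
# pipeline preserves the distance structure of the tract data; small maximum
# path lengths (a few hops, a few tens of ms) are the small-world property
# that lets perturbations cross the hemisphere quickly.
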