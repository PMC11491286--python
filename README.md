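# mesocortex

A mesoconnectome builder and spiking network model of one hemisphere of
human cerebral cortex, for computational neuroscientists who want a
data-driven, population-resolved model of human cortical structure and
resting-state dynamics that runs — down-scaled — on a workstation.

Each of the 34 areas of the Desikan–Killiany parcellation is a 1 mm²
cortical column with layers 2/3, 4, 5, 6, each split into excitatory and
inhibitory populations of leaky integrate-and-fire neurons with exponential
postsynaptic currents. The package

- **builds the mesoconnectome** from tabular anatomy: neuron numbers
  N = ρ_neuron · h_layer · A_column per layer; a synapse budget
  ρ_synapse · V per area (ρ_synapse = 6.6×10⁸ /mm³); a long-range fraction
  from the white-matter scaling rule N_nonlocal/N_total ∝ N_total^(−0.16)
  (0.14 for human cortex); a column-internal vs. within-area split from
  cylindrical integrals of the exp(−d/λ_conn) connection profile
  (λ_conn = 160 µm); a layered-microcircuit blueprint for local
  connectivity; streamline counts for area-level long-range weights; the
  probit law SLN = Φ(a₀ + a₁ ln(ρ_target/ρ_source)) for laminar origins;
  SLN-dependent target patterns, dendritic-length routing of postsynaptic
  somata, and a fixed 93% excitatory target share for feedback projections;
- **simulates** explicit network realizations (random, fixed-total-number
  connectivity; weights from 0.1 mV PSPs with g = 5 inhibition and
  inter-areal scaling factors χ, χ_I; truncated log-normal delays) with a
  deterministic native engine whose per-neuron random streams make
  exactly-paired single-spike perturbation experiments possible;
- **analyzes** activity the way the experimental comparisons require:
  rates, CV ISI, revised local variation (LvR), pairwise correlations,
  Kolmogorov–Smirnov similarity, a BOLD proxy (per-area summed |synaptic
  current|) with functional-connectivity similarity measures, temporal
  hierarchy from cross-correlation delays, and perturbation propagation.

A synthetic-anatomy generator reproduces the statistical structure of the
real inputs (log-normal streamline counts with exponential distance decay,
plausible cytoarchitecture), so the full pipeline runs and is tested
without any data download. Real tables, when available, are consumed from
the same CSV formats.

## Worked example

`examples/01_build_connectome.py` builds the full 34-area synthetic model:

```
areas:           34
populations:     272 with neurons (272 slots)
total neurons:   3.51 million
total synapses:  44.4 billion

pericalcarine synapse budget (primary visual cortex):
  N_total      1,212,174,591
  N_local      1,039,787,096
  N_nonlocal     172,387,495
  N_internal     629,571,722
  N_external     410,215,374
```

The model carries the full biological density: ~3.5 million neurons and
~44 billion synapses per hemisphere. Each area's budget splits into
column-internal synapses, synapses from the rest of the area (replaced by
Poisson drive), and long-range synapses (the 0.14 fraction).
`examples/02_structural_validation.py` then checks structure that was not
built in:

```
log10 synapse counts: mean 4.98, sd 0.81
distance decay constant: 45.5 mm (generator used 45.0 mm)
mean outdegree by direction: FF=nan, LAT=82, FB=123
mean #target areas (outdegree>100): FF=nan, LAT=5.98, FB=2.85
max shortest path (hops): 3
max delay-weighted path:  36.5 ms
```

Synapse counts span several orders of magnitude (log-normal-like), the
fitted distance-decay constant recovers the generating 45 mm, and the
population graph is small-world: any population reaches any other in at
most 3 hops and ≤ 37 ms of summed mean delays. (On synthetic anatomy the
feedforward class can be empty — cytoarchitecture and connectivity are
drawn independently — hence the NaN; see `docs/methods.md`.)

The remaining examples simulate a down-scaled network and reproduce the
dynamical analyses: `03_simulate_network.py` (spiking statistics and
BOLD-proxy functional connectivity), `04_single_spike_perturbation.py`
(one extra spike alters every area's spike pattern within tens of
milliseconds), `05_temporal_hierarchy.py` (leading/lagging order of areas
from cross-correlation delays).

A thin command-line interface wraps the same library calls:

```bash
mesocortex gen-anatomy --seed 1 --out anat/
mesocortex build-connectome --anatomy anat/ --out conn/
mesocortex validate-connectome --anatomy anat/ --connectome conn/ --out report.json
mesocortex simulate --anatomy anat/ --connectome conn/ --chi 2.5 \
    --scale 0.01 --duration 10000 --out run/
mesocortex analyze --run run/ --out analysis/
```

## Layout

- `src/mesocortex/anatomy.py`, `synth.py` — anatomical inputs: types, CSV
  round-trip, cytoarchitecture aggregation, synthetic generator
- `src/mesocortex/geometry.py` — column integrals of the local connection
  profile (quadrature + Monte-Carlo cross-check)
- `src/mesocortex/connectome.py`, `validation.py` — the mesoconnectome
  builder and its structural validation statistics
- `src/mesocortex/params.py`, `network.py`, `simulation.py` — model
  parameters, network realization, native simulation engine
- `src/mesocortex/analysis.py`, `hierarchy.py` — activity statistics,
  similarity measures, temporal hierarchy, perturbation propagation
- `src/mesocortex/workflow.py`, `config.py`, `cli.py`, `io.py`,
  `plotting.py` — reproducible end-to-end runs, χ sweep, file formats,
  figures
- `docs/methods.md` — full model description, numerical choices, and what
  the synthetic data does and does not establish
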