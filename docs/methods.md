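# Methods

`mesocortex` builds a population-resolved synapse-count matrix
("mesoconnectome") for the 34 areas of one hemisphere in the
Desikan–Killiany parcellation, instantiates down-scalable spiking networks
from it, and analyzes the simulated activity. This note documents the model,
its parameters, the numerical choices, and what the synthetic data generator
does and does not emulate.

## Model construction

Each area is a 1 mm² cortical column with layers 2/3, 4, 5 and 6, each split
into an excitatory (E) and an inhibitory (I) population (at most 8
populations per area; layers of zero thickness — agranular areas — keep
empty slots so that all matrices index uniformly).

**Neuron numbers.** Per layer, N = round(ρ_neuron · h_layer · A_column) with
the layer's volume density ρ_neuron (neurons/mm³), thickness h_layer (mm)
and A_column = 1 mm². The excitatory count is round(N · f_E) with layer-wise
excitatory fractions defaulting to 0.65 / 0.79 / 0.78 / 0.86 for layers
2/3 / 4 / 5 / 6 (electron-microscopy estimates from human temporal lobe).
Where cytoarchitectonic tables resolve finer subdivisions than one target
area, `aggregate_vek_to_dk` sums sub-layer thicknesses, averages thicknesses
across sub-areas, and thickness-weights the density average.

**Synapse budget.** A constant synapse volume density ρ_synapse =
6.6×10⁸ /mm³ gives each area a total budget N_total = round(ρ_synapse ·
A_column · Σ h_layer). Layer 1 carries no neurons; its thickness is kept
separately because long-range synapses terminate there.

**Local vs. long-range split.** The fraction of neurons sending axons into
the white matter scales with the total gray-matter neuron count N as
N^(−0.16); calibrated with 0.21 at 1.4×10⁹ neurons and evaluated at 16×10⁹
this gives 0.14 for human cortex. The same fraction is applied to synapses:
N_nonlocal = round(0.14 · N_total).

**Column-internal vs. within-area external.** Local connectivity follows an
isotropic exponential profile exp(−d/λ_conn), λ_conn = 0.16 mm. Modeling the
column and its area as concentric cylinders of equal height, the probability
masses of (both endpoints inside the column) and (presynaptic endpoint in
the annulus) are two six-dimensional integrals. After analytic reduction of
the angular and vertical difference coordinates they become 3-D integrals
over (r₁, r₂, φ) of r₁ r₂ K(d_xy), where K(u) = ∫₀ʰ (h−z) e^(−√(u²+z²)/λ) dz
and d_xy² = (r₁−r₂)² + 4 r₁ r₂ sin²(φ/2). These are evaluated with a
tabulated K (composite Gauss) and panelized Gauss–Legendre quadrature in
difference coordinates ρ = r₁ − r₂ — the kernel ridge sits at ρ ≈ 0, so the
panel count stays logarithmic in λ — with mesh-doubling error control at
relative tolerance 10⁻³ (`QuadratureError` carries the achieved tolerance on
failure). A Monte-Carlo estimator of the same quantities (postsynaptic point
uniform in the column, displacement from the normalized exponential kernel,
radius ~ Gamma(3, λ)) serves as fallback and independent cross-check; the
two agree to well under 2% across the realistic parameter range. The ratio
ρ_internal : ρ_external splits the local budget.

**Within-column connectivity.** Internal synapses are distributed over the
8×8 population pairs proportionally to N_B · q[A,B] · N_A, where q is the
relative number of synapses per neuron pair of a standard layered
microcircuit blueprint (shipped default: −ln(1−p) of the published
connection probabilities of the 8-population microcircuit model, which is
proportional to the expected synapse count per pair under the
fixed-total-number rule). External local synapses become per-population
external-drive synapse counts proportional to k_ext[A] · N_A, with the
blueprint's reference external indegrees fixing only the relative values.

**Long-range projections.** The non-local budget of a target area is
distributed over source areas by relative streamline counts (NoS);
self-connections are excluded and an isolated area is an error. The laminar
origin follows the predicted fraction of supragranular labeled neurons,
SLN(B→A) = Φ(a₀ + a₁ ln(ρ_A/ρ_B)) with a₀ = −0.152, a₁ = −1.534 (probit fit
to macaque retrograde tracing, applied to human area-level densities
computed as total neurons / total volume). A fraction SLN of a projection's
synapses originates from 2/3E; the remainder is split between 5E and 6E by
relative population size; layer 4 and inhibitory neurons never project
between areas. Target layers follow three SLN categories: feedforward
(SLN > 0.65) terminates in layer 4 (layer 2/3 for agranular targets),
lateral (0.35 ≤ SLN ≤ 0.65) spreads over layers 1, 2/3, 4, 5, 6, and
feedback (SLN < 0.35) avoids layer 4; within a pattern, weights are
proportional to layer thickness. Boundary SLN values belong to the lateral
class. Each synapse layer has a configurable probability that the
postsynaptic neuron is excitatory; excitatory targets are routed to soma
layers through the dendritic-length matrix P(soma in B | synapse in A) =
ℓ_AB / Σ_B ℓ_AB and the synapse location marginalized out, inhibitory
targets sit in the synapse's own layer. For feedback projections the total
excitatory target share is fixed at 93%. Layer 1 has no neurons: its
inhibitory share is reassigned proportionally to the other layers'
inhibitory shares (and to the excitatory targets if no layer has any
inhibitory share); its excitatory share is already routed through the
dendritic profile. Weights falling on populations with zero neurons are
dropped and the rest renormalized, which makes agranular layer-4 slots
exactly silent.

**Rounding.** Every integer allocation uses nearest-integer rounding with
largest-remainder reconciliation (`allocate_integers`), so each partition
sums exactly to its parent budget; per-area budgets are recorded in
`SynapseCounts.bookkeeping` and asserted in the tests.

## Structural validation

`validate_connectome` computes: mean/SD of log₁₀ synapse counts over nonzero
population pairs; the exponential distance decay as OLS of ln(area-pair
count) on fiber length (decay constant −1/slope; a non-negative slope
reports an infinite constant rather than an error); mean outdegrees per
direction class (FF/LAT/FB by predicted SLN; outdegree = projection synapses
/ source population size); mean number of target areas per source population
counting only projections with outdegree > 100 (filter applied before
classification, averaged over source populations with at least one
qualifying target); and unweighted plus mean-delay-weighted shortest-path
statistics on the directed population graph (scipy.sparse.csgraph).

## Spiking model

Leaky integrate-and-fire neurons with exponential postsynaptic currents:
τ_m = 10 ms, C_m = 220 pF (E) / 100 pF (I), V_th = −45 mV, E_L = V_reset =
−70 mV, τ_r = 2 ms, τ_s = 2 ms. PSPs convert to currents via PSC/PSP =
(C_m/τ_m) ε^(−1/(1−ε)), ε = τ_s/τ_m, using the *target's* capacitance
(16.4 pA onto E, 7.5 pA onto I for a 0.1 mV PSP). Weights are normal with
relative SD 10%, redrawn on sign violation; inhibitory-source weights are −g
times the excitatory ones (g = 5); within-area 4E→2/3E weights are doubled;
inter-areal weights are scaled by χ (1 = base version, 2.5 = best-fitting)
and additionally by χ_I = 2 onto inhibitory targets (applied for every χ;
both configurable). Delays are truncated log-normal with relative SD 50%
(draws below one step redrawn, then rounded to the 0.1 ms grid): means
1.5 ms / 0.75 ms for local excitatory / inhibitory sources and fiber length
÷ 3.5 m/s between areas. Connectivity is "random, fixed total number":
exactly the specified synapse count per projection, endpoints drawn with
replacement (autapses/multapses allowed), realized by a per-source-neuron
multinomial split and stored CSR-by-source in compact dtypes (int32 targets,
float32 weights, int16 delay steps) so that a 1%-scale hemisphere
(≈3×10⁸ synapses) fits comfortably in memory.

**External drive.** Each population receives independent Poisson input on
its K_ext = N_ext→A / N_A drive synapses at rate ν = (V_th−E_L) η /
(τ_m w_ext K_ext), η = 1.1, w_ext = 0.1 mV, with weights additionally scaled
by 1.05 (5E) and 1.15 (6E). The rate formula treats each PSP as an
instantaneous voltage kick of w·τ_m; for exponential PSCs the realized mean
current overshoots η × rheobase by ε^(−ε/(1−ε)) ≈ 1.50. Both conventions are
provided: the default evaluates the formula verbatim; `strict_eta=True`
divides the rate by the overshoot factor so the mean current is exactly
η × rheobase. The printed 35–50 spikes/s range for an isolated neuron holds
in strict mode (measured ≈ 37 spikes/s); the verbatim mode drives an
isolated neuron at ≈ 87 spikes/s. The 5E/6E factors scale only the synaptic
weight (raising the mean input), not the rate.

**Integration.** Exact propagator of the linear (V, I) system on a fixed
0.1 ms grid; spikes are detected after the update, stamped on the grid, and
the membrane is clamped at V_reset for τ_r (current states keep evolving).
Spike delivery uses a ring buffer indexed by arrival step. Initial membrane
potentials are drawn per neuron uniformly in [V_reset, V_th]. An optional
constant-current input supports closed-form checks (the deterministic
inter-spike period τ_r + τ_m ln(μ/(μ−V_th+E_L)) is reproduced within one
step), and selected neurons' voltages can be recorded (the engine-level
single-PSP test reproduces the 0.1 mV peak within 0.5%).

**Random streams and paired runs.** Every neuron owns a counter-based
Philox stream keyed by (seed, neuron id) supplying its initial state and
Poisson drive, consumed independently of network activity. Two runs with the
same seed therefore draw identical random numbers; the paired-perturbation
protocol simulates the same realization twice, once with one neuron's
membrane potential forced above threshold at a chosen grid time. Control
runs are event-identical; differences in the perturbed run are causal
consequences of the single extra spike.

**Down-scaling.** `scale` multiplies neuron and synapse counts equally,
preserving indegrees and synaptic weights (the full-density
parameterization). An optional variant multiplies weights by 1/√scale to
preserve input fluctuations; it is off by default because it deviates from
the full-density definition. Projections whose endpoints scale to zero
neurons are dropped with a logged warning. Distributed neuron parameters
(log-normal V_th, C_m, τ_m with configurable CVs) are available behind
`NeuronParams.cv_table` and default to off; the weight conversion keeps
using the population means.

## Activity analysis

Rates are spike counts over the analysis window (comparison sets keep
neurons ≥ 0.5 spikes/s; raw rates report everyone, silent neurons as 0).
CV ISI and LvR require ≥ 10 spikes; LvR = 3/(n−1) Σ [1 − 4 I_i I_{i+1} /
(I_i+I_{i+1})²][1 + 4R/(I_i+I_{i+1})] with refractoriness constant R = 5 ms
by default (R = 0 recovers the plain local variation; both are 1 for a
Poisson process). Pairwise correlations use 1 ms binned counts of a seeded
random subsample of 2000 neurons per population (zero-variance trains
dropped and logged). Distribution similarity is 1 − KS distance; simulated
activity is split into 5 equal snippets of the 10 s analysis window to
mirror short recordings, and the first 2500 ms of every simulation are
discarded as transient by default. The fMRI proxy is the per-area sum of
|synaptic current| per neuron, sampled every 1 ms (external drive included
by default, excludable by flag); functional connectivity is its Pearson
correlation matrix, compared to a reference FC by the off-diagonal Pearson
correlation and by exp(−RMSE/σ_exp). A deliberate omission: no hemodynamic
(Balloon–Windkessel) model — the proxy acts directly on summed synaptic
inputs.

**Temporal hierarchy.** Area-level rate signals (layer-aggregated spikes,
1 ms bins) are cross-correlated after mean subtraction within ±100 ms lag.
The peak lag is the pairwise delay; when several local maxima lie within 5%
of the global maximum ("peaks of similar height" — the 5% is this package's
quantification), the delay closest to zero is used if all candidates share a
sign (a candidate at zero decides as zero), otherwise the pair is undecided.
Delays whose per-segment estimates (9 segments) have a median absolute
deviation above 3 ms are rejected. The ordering minimizes Σ (delay_ij −
β(rank_j − rank_i))² with β ≥ 0 fit per ordering — exhaustively for ≤ 8
areas, greedy insertion plus pairwise-swap refinement above that. The delay
matrix is antisymmetric on decided pairs.

**Perturbation propagation.** Spikes of both paired runs are counted per
population in 0.1 ms bins; the first bin with a nonzero count difference
defines the population's first-difference time, areas take the earliest of
their populations, and the summary is the mean ± SD over areas relative to
the perturbation time. Identical records yield a trace flagged
`no_propagation`.

## Synthetic anatomy

`synth_anatomy` emulates the statistical structure of the real inputs so the
entire pipeline runs without downloads: area centers uniform on a sphere of
radius 60 mm (chord distances span the range of human inter-areal fiber
lengths); symmetric streamline counts log-normal (default ln-scale mean 7.0,
SD 1.0) multiplied by exp(−distance/45 mm); layer thicknesses and volume
densities uniform within human cortical ranges (densities 25–75 ×10³/mm³,
total thickness ≈ 1.2–3.0 mm plus 0.1–0.3 mm of layer 1; surfaces
400–2500 mm²). With 34 areas this yields ≈ 3.5 million neurons and
≈ 44 billion synapses — the scale of the real single-hemisphere model. The
generator returns its parameters so recovery tests can fit them back (decay
constant and log-normal parameters are recovered within 15% over 20 seeds).
What it does **not** emulate: the empirical correlation between
cytoarchitecture and connectivity (SLN values on synthetic bundles are
uniform-ish rather than bimodal, so feedforward projections can be rare),
hemispheric geometry beyond a sphere, area-specific E/I fractions, and any
real dendritic morphology (the default dendritic-length matrix is a
synthetic placeholder with plausible diagonal dominance and layer-1 apical
reach). Passing tests on synthetic bundles therefore validates the
*machinery* — budgets, allocation, conservation, statistics — not the
biological numbers, which require the real tables (placed under
`data/real/`, see `tests/test_acceptance.py`).

## Problem sizes used in tests and examples

The test suite and examples run down-scaled models chosen to exercise every
code path at desk scale: unit fixtures use 2–6 synthetic areas at
scale 10⁻³–5×10⁻³; the perturbation acceptance check runs the full 34-area
synthetic model at scale 0.01 (≈ 35 000 neurons, ≈ 3×10⁸ synapses, 100 ms);
the isolated-neuron drive check runs 50 s of a single neuron. Full-scale
simulation (scale 1, 3.5×10⁶ neurons, 4×10¹⁰ synapses) is out of the test
surface; the data structures support it in principle but a cluster-class
machine and/or the optional export to an external simulator would be needed.

## Known limitations

- No spatial neuron positions, no plasticity, conductance synapses,
  adaptation or neuromodulation; external input is exclusively excitatory
  and stationary.
- The E/I target probabilities per synapse layer ship as a documented
  placeholder vector; real analyses should supply the measured aggregate.
- The outdegree statistic is computed per projection and then averaged;
  published corrections multiplying by surface ratios are not applied.
- The mean-field comparison in the tests uses the diffusion approximation
  with a first-order colored-noise boundary shift; agreement is expected
  only at the tens-of-percent level in strongly coupled regimes.
- The temporal-hierarchy ordering optimizer is exact only for ≤ 8 areas;
  above that a greedy + swap heuristic is used.
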