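"""Build the mesoconnectome of a synthetic 34-area hemisphere.

Generates a statistics-matched synthetic anatomy bundle (log-normal
streamline counts with exponential distance decay, plausible human layer
thicknesses and neuron densities), assembles the population-level synapse
count matrix, and prints the resulting scale of the model.
"""

from mesocortex import assemble_connectome, synth_anatomy

bundle, spec = synth_anatomy(seed=1, n_areas=34)
grid, counts = assemble_connectome(bundle)

print(f"areas:           {bundle.n_areas}")
print(f"populations:     {int(grid.exists.sum())} with neurons "
      f"({grid.n_populations} slots)")
print(f"total neurons:   {grid.total_neurons / 1e6:.2f} million")
print(f"total synapses:  {counts.total_synapses / 1e9:.1f} billion")
bk = counts.bookkeeping["pericalcarine"]
print("\npericalcarine synapse budget (primary visual cortex):")
for key, val in bk.items():
    print(f"  {key:11s} {val:>14,d}")

# The totals show the model carries the full biological synapse density:
# a few million neurons and tens of billions of synapses per hemisphere,
# with each area's budget split into column-internal, within-area external,
# and long-range synapses.
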