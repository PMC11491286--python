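"""The 34 cortical areas of one hemisphere in the Desikan-Killiany parcellation.

Every matrix and population index in the package uses this fixed area order.
"""

# (long name, acronym) pairs, packaged verbatim in the conventional table order.
DK_AREAS: list[tuple[str, str]] = [
    ("bankssts", "BSTS"),
    ("caudalanteriorcingulate", "CAC"),
    ("caudalmiddlefrontal", "CMF"),
    ("cuneus", "CUN"),
    ("entorhinal", "ENT"),
    ("fusiform", "FUS"),
    ("inferiorparietal", "INFP"),
    ("inferiortemporal", "IT"),
    ("isthmuscingulate", "ISTC"),
    ("lateraloccipital", "LOCC"),
    ("lateralorbitofrontal", "LORB"),
    ("lingual", "LIN"),
    ("medialorbitofrontal", "MORB"),
    ("middletemporal", "MT"),
    ("parahippocampal", "PARH"),
    ("paracentral", "PARC"),
    ("parsopercularis", "POPE"),
    ("parsorbitalis", "PORB"),
    ("parstriangularis", "PTRI"),
    ("pericalcarine", "PCAL"),
    ("postcentral", "PSTS"),
    ("posteriorcingulate", "PC"),
    ("precentral", "PREC"),
    ("precuneus", "PCUN"),
    ("rostralanteriorcingulate", "RAC"),
    ("rostralmiddlefrontal", "RMF"),
    ("superiorfrontal", "SF"),
    ("superiorparietal", "SP"),
    ("superiortemporal", "ST"),
    ("supramarginal", "SMAR"),
    ("frontalpole", "FP"),
    ("temporalpole", "TP"),
    ("transversetemporal", "TT"),
    ("insula", "INS"),
]

DK_NAMES: list[str] = [name for name, _ in DK_AREAS]
DK_ACRONYMS: dict[str, str] = dict(DK_AREAS)

#: Layers represented by neuron populations in the model.
LAYERS: tuple[str, ...] = ("2/3", "4", "5", "6")

#: Layers in which a synapse can be located (layer 1 holds synapses but no somata).
SYNAPSE_LAYERS: tuple[str, ...] = ("1", "2/3", "4", "5", "6")

#: Population labels of a fully granular area, in canonical order.
POPULATION_LABELS: tuple[str, ...] = (
    "2/3E", "2/3I", "4E", "4I", "5E", "5I", "6E", "6I",
)
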