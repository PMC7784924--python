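"""Taxonomic rank constants shared across the package."""

#: Ranks carried by a placement, root-most first.
LEVELS = ("phylum", "class", "order", "family", "genus", "species")

#: Ranks at which the hierarchical clustering operates (phylum is fixed by
#: the fungal-retention filter upstream).
CLUSTER_LEVELS = ("class", "order", "family", "genus", "species")

LEVEL_INDEX = {name: i for i, name in enumerate(LEVELS)}
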