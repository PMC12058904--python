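"""Classify a single network given as an extended Newick string.

The reticulation vertex appears twice under the shared #H1 tag.  The
classifier reports where the network sits in the hierarchy, its
shortcut edges, a temporal ranking when one exists (dates constant on
each reticulation and its parents, strictly increasing along tree
edges), and the displayed trees.
"""

from arcnets import (classify, displayed_trees, parse_enewick, shortcuts,
                     temporal_ranking, write_newick)

ENW = "(((2)#H1,1),(#H1,3));"  # one hybrid: taxon 2's lineage is shared

g = parse_enewick(ENW)
label = classify(g)
print("input:          ", ENW)
print("classification: ", label.value, f"(coarse: {label.coarse})")
print("shortcut edges: ", sorted(shortcuts(g)) or "none")
print("temporal dates: ", temporal_ranking(g))
print("displayed trees:", [write_newick(t) for t in displayed_trees(g)])
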