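"""Score predictions by ontology distance instead of exact match.

A near-miss prediction (the parent or a sibling of the asserted class)
is more useful than one in a distant branch.  This example builds a
small hierarchy, condenses redundant superclass predictions, and
computes the pairwise path-length report and mean parent count.
"""

import networkx as nx

from chemont import OntologyGraph, mean_parent_count, path_length_report

# root <- {acid, alcohol}; acid <- {carboxylic, sulfonic}
g = nx.DiGraph()
g.add_edges_from([
    ("acid", "root"), ("alcohol", "root"),
    ("carboxylic", "acid"), ("sulfonic", "acid"),
])
ontology = OntologyGraph(graph=g, root="root")

asserted = {"m1": {"carboxylic"}, "m2": {"carboxylic"}, "m3": {"carboxylic"}}
predicted = {
    "m1": {"carboxylic"},          # exact match            -> distance 0
    "m2": {"sulfonic"},            # sibling                -> distance 2
    "m3": {"carboxylic", "acid"},  # class + its superclass -> condensed
}
condensed = {m: ontology.condense(p) for m, p in predicted.items()}
print(f"m3 condensed from {sorted(predicted['m3'])} to {sorted(condensed['m3'])}")

report = path_length_report(ontology, asserted, condensed)
for m in sorted(report.pairwise):
    print(f"{m}: pairwise lengths {report.pairwise[m]}")
print(f"mean path length = {report.mean:.3f} (0 would be all exact matches)")
print(f"mean parent count = {mean_parent_count(predicted, ontology):.3f}")
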