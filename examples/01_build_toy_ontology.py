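"""Generate a toy chemical ontology and inspect its structure.

Builds a small single-rooted subsumption DAG whose leaf terms carry
SMILES with a class-specific motif, writes it as an OBO file, reloads
it, and prints the class/member breakdown.
"""

from pathlib import Path

from chemont import FixtureSpec, load_ontology, make_toy_ontology

out = Path("toy.obo")
ontology = make_toy_ontology(
    FixtureSpec(n_classes=3, members_per_class=5, overlap_fraction=0.2, seed=1),
    path=out,
)
reloaded = load_ontology(out, root=ontology.root)

leaves = reloaded.leaf_members()
print(f"terms: {len(reloaded)}, leaf members with structures: {len(leaves)}")
for cid in sorted(reloaded.children(reloaded.root)):
    members = reloaded.descendants(cid) & leaves
    print(f"  {cid} ({reloaded.name(cid)}): {len(members)} leaf members")
example = sorted(leaves)[0]
print(f"example leaf {example}: SMILES {reloaded.smiles(example)}")
# The leaf counts can exceed members_per_class because a 0.2 overlap
# fraction attaches some leaves beneath a second class as well — the
# diamond structure that makes non-overlapping sampling non-trivial.
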