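"""Draw a balanced N x M dataset and split it for learning.

Samples 3 classes x 8 disjoint leaf members from a toy ontology using
the smallest-first strategy, then splits 70/10/20 stratified by class.
"""

from chemont import DatasetSpec, FixtureSpec, make_toy_ontology, select_balanced, split

ontology = make_toy_ontology(
    FixtureSpec(n_classes=4, members_per_class=12, overlap_fraction=0.3, seed=2)
)
dataset = select_balanced(ontology, DatasetSpec(n_classes=3, members_per_class=8, seed=2))

for cid, members in dataset.assignments.items():
    print(f"{cid}: {len(members)} members, e.g. {members[0].id} = {members[0].smiles}")

all_ids = [m.id for ms in dataset.assignments.values() for m in ms]
print(f"total members: {len(all_ids)}, distinct: {len(set(all_ids))} (disjointness)")

parts = split(dataset, (0.7, 0.1, 0.2), seed=2)
print(
    f"split sizes: train={len(parts.train)} validation={len(parts.validation)} "
    f"test={len(parts.test)}"
)
# 3 classes x 8 members = 24 records; stratification keeps each class's
# share of every partition within one record of the exact proportion.
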