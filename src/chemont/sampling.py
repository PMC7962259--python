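"""Balanced, non-overlapping dataset construction from an ontology.

Chemical ontologies are heavily multi-parented: a leaf structure
typically sits below many overlapping classes.  To obtain a clean
supervised problem, N classes are selected and M leaf members sampled
for each such that (a) every class receives exactly M members and
(b) no member is assigned to more than one class.  Candidate classes
are processed from the smallest leaf-member count to the largest, so
that small classes — whose members are most likely to be swallowed by
larger subsuming classes — are filled first and the sub-sampling
distorts the ontology as little as possible.

The resulting N x M dataset is then split (stratified by class) into
train / validation / test partitions; the validation share may be zero
for classifiers without hyper-parameters to tune.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .ontology import OntologyGraph

__all__ = [
    "DatasetSpec",
    "Member",
    "SampledDataset",
    "Record",
    "SplitDataset",
    "InfeasibleSpecError",
    "select_balanced",
    "split",
]


class InfeasibleSpecError(ValueError):
    """The ontology cannot supply N disjointly-filled classes of size M."""


@dataclass(frozen=True)
class DatasetSpec:
    """Problem size: N classes x M members per class, plus the sampling seed."""

    n_classes: int
    members_per_class: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.members_per_class < 1:
            raise ValueError("members_per_class must be >= 1")


class Member(NamedTuple):
    id: str
    smiles: str


@dataclass
class SampledDataset:
    """A balanced class -> members assignment.

    Invariants: exactly ``spec.n_classes`` keys, every list has exactly
    ``spec.members_per_class`` entries, member ids are globally unique,
    and each member lies in the descendant leaf closure of its class.
    """

    assignments: dict[str, list[Member]]
    spec: DatasetSpec

    @property
    def classes(self) -> list[str]:
        return list(self.assignments)

    def records(self) -> list[tuple[str, str, str]]:
        """Flatten to (member_id, smiles, class_id) rows."""
        return [
            (m.id, m.smiles, cid)
            for cid, members in self.assignments.items()
            for m in members
        ]


class Record(NamedTuple):
    member_id: str
    smiles: str
    class_id: str


@dataclass
class SplitDataset:
    train: list[Record]
    validation: list[Record]
    test: list[Record]
    fractions: tuple[float, float, float]

    def partition(self, name: str) -> list[Record]:
        return getattr(self, name)

    def to_tsv(self, path: str | Path) -> None:
        """Columns: member_id, smiles, class_id, split."""
        with open(path, "w") as fh:
            fh.write("member_id\tsmiles\tclass_id\tsplit\n")
            for part in ("train", "validation", "test"):
                for rec in self.partition(part):
                    fh.write(f"{rec.member_id}\t{rec.smiles}\t{rec.class_id}\t{part}\n")


def leaf_closure(graph: OntologyGraph, class_id: str) -> set[str]:
    """Leaf members in the strict descendant closure of a class."""
    return graph.descendants(class_id) & graph.leaf_members()


def candidate_classes(graph: OntologyGraph) -> list[tuple[str, int]]:
    """Terms eligible as classes, smallest leaf closure first.

    A class must subsume at least two leaf members.  Ties in size break
    by ascending term identifier so the ordering is deterministic.
    """
    sizes = []
    leaves = graph.leaf_members()
    for term in graph.terms:
        if term in leaves:
            continue
        n = len(graph.descendants(term) & leaves)
        if n >= 2:
            sizes.append((term, n))
    sizes.sort(key=lambda t: (t[1], t[0]))
    return sizes


def select_balanced(graph: OntologyGraph, spec: DatasetSpec) -> SampledDataset:
    """Greedy smallest-first balanced selection of N x M disjoint members.

    Candidate classes are visited in ascending order of leaf-member
    count.  A class is filled when at least M of its leaf members are
    still unused: M of them are drawn uniformly at random without
    replacement and marked used; otherwise the class is skipped and the
    iteration continues.  Selection stops after N classes.

    Raises
    ------
    InfeasibleSpecError
        When fewer than N classes can be disjointly filled, reporting
        how many were fillable.
    """
    rng = np.random.default_rng(spec.seed)
    used: set[str] = set()
    leaves = graph.leaf_members()
    assignments: dict[str, list[Member]] = {}
    for class_id, _size in candidate_classes(graph):
        if len(assignments) == spec.n_classes:
            break
        available = sorted((graph.descendants(class_id) & leaves) - used)
        if len(available) < spec.members_per_class:
            continue
        chosen = rng.choice(
            len(available), size=spec.members_per_class, replace=False
        )
        members = [
            Member(available[i], graph.smiles(available[i]) or "")
            for i in sorted(chosen)
        ]
        used.update(m.id for m in members)
        assignments[class_id] = members
    if len(assignments) < spec.n_classes:
        raise InfeasibleSpecError(
            f"requested {spec.n_classes} classes x {spec.members_per_class} "
            f"disjoint members but only {len(assignments)} classes were fillable"
        )
    return SampledDataset(assignments=assignments, spec=spec)


def _allot(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment: each count within 1 of n*f."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(3), key=lambda i: (raw[i] - counts[i]), reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split(
    dataset: SampledDataset,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SplitDataset:
    """Stratified-by-class random train/validation/test partition.

    Fractions must be non-negative and sum to 1 (within 1e-9); the
    validation fraction may be zero — classifiers without
    hyper-parameters use a two-way split.  Per-class partition sizes
    deviate from the exact proportions by at most one record, and the
    partition is reproducible from ``seed``.
    """
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative proportions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[Record]] = {"train": [], "validation": [], "test": []}
    for class_id in sorted(dataset.assignments):
        members = dataset.assignments[class_id]
        order = rng.permutation(len(members))
        n_train, n_val, n_test = _allot(len(members), tuple(fractions))
        shuffled = [members[i] for i in order]
        cursor = 0
        for name, count in (("train", n_train), ("validation", n_val), ("test", n_test)):
            for m in shuffled[cursor : cursor + count]:
                parts[name].append(Record(m.id, m.smiles, class_id))
            cursor += count
    return SplitDataset(
        train=parts["train"],
        validation=parts["validation"],
        test=parts["test"],
        fractions=tuple(fractions),
    )
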