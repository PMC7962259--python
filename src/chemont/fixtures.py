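"""Synthetic toy ontologies with motif-bearing SMILES leaves.

Real chemical ontologies are large, diamond-shaped (leaves sit below
many partially overlapping ancestor classes) and only available by
download.  This module generates miniature stand-ins with the same
structural features so that every pipeline stage — sampling, encoding,
training, evaluation — can be exercised offline and deterministically.

Class identity is encoded chemically: each class is assigned a
distinctive SMILES fragment (a *motif*, e.g. ``Cl`` or ``C#C``) and every
leaf of that class embeds the motif inside random valid decoration drawn
from a small grammar of acyclic carbon/oxygen/nitrogen chains with an
optional ring.  Validity is guaranteed by construction rather than
rejection sampling, and a linear classifier on fingerprints separates
the classes — the sanity anchor for all learning tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .ontology import OntologyGraph, write_obo

__all__ = [
    "FixtureSpec",
    "DEFAULT_MOTIFS",
    "make_toy_ontology",
    "random_valid_smiles",
]

#: Fragments usable as class motifs: each introduces a feature (halogen,
#: heteroatom, unsaturation, ring) absent from the decoration grammar of
#: the other classes, so classes are separable by substructure.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "Cl",
    "Br",
    "I",
    "F",
    "S",
    "P",
    "B",
    "C#C",
    "C=C",
    "C1CCCC1",
)

#: Chain atoms of the decoration grammar with their sampling weights.
_CHAIN_ATOMS = ("C", "C", "C", "C", "C", "O", "N")


class FixtureError(ValueError):
    """Invalid fixture specification."""


@dataclass
class FixtureSpec:
    """Shape of a generated toy ontology.

    Parameters
    ----------
    n_classes
        Number of mid-level classes (each gets one motif).
    members_per_class
        Leaves generated under each class.
    hierarchy_depth
        Levels from root to leaf inclusive; minimum 3
        (root -> class -> leaf).
    overlap_fraction
        Share of leaves attached beneath a second class as well, which
        reproduces the diamond-shaped multiple inheritance of real
        chemical ontologies.  In [0, 1).
    motifs
        One distinctive SMILES fragment per class; defaults to a prefix
        of :data:`DEFAULT_MOTIFS`.
    seed
        Seed for the generator; same spec -> same ontology.
    """

    n_classes: int = 5
    members_per_class: int = 20
    hierarchy_depth: int = 3
    overlap_fraction: float = 0.0
    motifs: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.members_per_class < 1:
            raise FixtureError("n_classes and members_per_class must be >= 1")
        if self.hierarchy_depth < 3:
            raise FixtureError("hierarchy_depth must be >= 3 (root, class, leaf)")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise FixtureError("overlap_fraction must lie in [0, 1)")
        if self.motifs is None:
            if self.n_classes > len(DEFAULT_MOTIFS):
                raise FixtureError(
                    f"only {len(DEFAULT_MOTIFS)} default motifs available; "
                    "pass an explicit motif list"
                )
            self.motifs = DEFAULT_MOTIFS[: self.n_classes]
        else:
            self.motifs = tuple(self.motifs)
        if len(self.motifs) != self.n_classes:
            raise FixtureError("motif list length must equal n_classes")


def _random_chain(rng: np.random.Generator, length: int) -> str:
    """A random acyclic chain with occasional single-atom branches."""
    out: list[str] = []
    for _ in range(length):
        atom = _CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))]
        out.append(atom)
        if atom == "C" and rng.random() < 0.2:
            out.append("(C)")
    return "".join(out)


def random_valid_smiles(
    seed: int | np.random.Generator,
    length_range: tuple[int, int] = (4, 12),
    motif: str = "",
) -> str:
    """Generate a syntactically valid SMILES string.

    The backbone is a random acyclic C/O/N chain that may end in a
    cyclopentane-like ring; when a ``motif`` is given it is grafted as a
    branch on a backbone carbon (``C(<motif>)``), which keeps monovalent
    motifs such as halogens chemically valid.  The backbone chain-atom
    count falls within ``length_range``.  Deterministic for an integer
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = length_range
    total = int(rng.integers(lo, hi + 1))
    pre = int(rng.integers(1, max(2, total)))
    graft = f"C({motif})" if motif else ""
    smiles = _random_chain(rng, pre) + graft + _random_chain(rng, max(1, total - pre))
    if rng.random() < 0.3:
        # ring closure digit must not collide with one used by the motif
        digit = "1" if "1" not in motif else "2"
        smiles += f"C{digit}CCCC{digit}"
    return smiles


def _check_motif(motif: str) -> None:
    from rdkit import Chem

    probe = f"C({motif})C"
    if Chem.MolFromSmiles(probe) is None:
        raise FixtureError(f"motif {motif!r} is not embeddable into valid SMILES")


def make_toy_ontology(
    spec: FixtureSpec,
    path: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> OntologyGraph:
    """Build a single-rooted toy subsumption DAG with SMILES leaves.

    The hierarchy is root -> (chain of intermediate classes, when
    hierarchy_depth > 3) -> class terms -> leaves.  Each leaf carries a
    SMILES embedding its class's motif; a ``spec.overlap_fraction``
    share of leaves additionally gets a second parent class.  When
    ``path`` is given the graph is also serialised as OBO (round-trip
    compatible with :func:`chemont.ontology.load_ontology`); a TSV leaf
    manifest (term_id, smiles, parent class ids) is written to
    ``manifest_path`` when given.
    """
    for motif in spec.motifs:  # type: ignore[union-attr]
        _check_motif(motif)
    rng = np.random.default_rng(spec.seed)
    g = nx.DiGraph()
    root = "TOY:0000001"
    g.add_node(root, name="chemical entity")

    # chain of intermediates below the root to reach the requested depth
    anchor = root
    for level in range(spec.hierarchy_depth - 3):
        node = f"TOY:00001{level:02d}"
        g.add_node(node, name=f"intermediate level {level + 1}")
        g.add_edge(node, anchor)
        anchor = node

    class_ids = []
    for i in range(spec.n_classes):
        cid = f"TOY:001{i:04d}"
        g.add_node(cid, name=f"class {i} ({spec.motifs[i]})")
        g.add_edge(cid, anchor)
        class_ids.append(cid)

    leaf_no = 0
    manifest: list[tuple[str, str, list[str]]] = []
    for i, cid in enumerate(class_ids):
        for _ in range(spec.members_per_class):
            leaf_no += 1
            lid = f"TOY:10{leaf_no:05d}"
            smiles = random_valid_smiles(rng, motif=spec.motifs[i])
            g.add_node(lid, name=f"member {leaf_no} of class {i}", smiles=smiles)
            g.add_edge(lid, cid)
            parents = [cid]
            if spec.n_classes > 1 and rng.random() < spec.overlap_fraction:
                other = class_ids[(i + 1 + int(rng.integers(spec.n_classes - 1))) % spec.n_classes]
                g.add_edge(lid, other)
                parents.append(other)
            manifest.append((lid, smiles, parents))

    ontology = OntologyGraph(graph=g, root=root)
    if path is not None:
        write_obo(ontology, path)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            fh.write("term_id\tsmiles\tparent_class_ids\n")
            for lid, smiles, parents in manifest:
                fh.write(f"{lid}\t{smiles}\t{';'.join(parents)}\n")
    return ontology
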