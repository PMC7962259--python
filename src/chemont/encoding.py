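"""Molecular input encodings: topological fingerprints and SMILES tokens.

Two families of encodings feed the classifiers:

* **Fingerprints** — fixed-length bit vectors hashing topological walks
  of length 1..n through the molecular graph (RDKit's path-based
  ``RDKFingerprint``; 1024 bits and n = 7 by default).  These serve the
  classical classifiers, which need fixed-size inputs.
* **Token sequences** — the SMILES string split either character by
  character, or with two-letter element symbols (Cl, Br, Si, ...)
  merged into single tokens so the model need not learn that ``C``
  followed by ``l`` denotes chlorine rather than carbon.  Multi-digit
  ring-closure pointers stay as individual digit tokens because they
  can grow without bound.  Token sequences feed the recurrent network
  via an integer vocabulary with reserved padding (0) and
  unknown-token (1) indices.

Both tokenisation modes satisfy the round-trip property: concatenating
the tokens reproduces the input string byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintConfig",
    "InvalidSmilesError",
    "fingerprint",
    "fingerprint_matrix",
    "tokenize_chars",
    "tokenize_atoms",
    "Vocabulary",
    "build_vocab",
    "encode_sequence",
    "encode_matrix",
    "PAD_INDEX",
    "UNK_INDEX",
]

PAD_INDEX = 0
UNK_INDEX = 1

#: Two-letter element symbols of the periodic table.  Used for greedy
#: atom-grouped tokenisation: an uppercase letter followed by a
#: lowercase letter forms one token iff the pair is in this set.
TWO_LETTER_ELEMENTS = frozenset(
    """He Li Be Ne Na Mg Al Si Cl Ar Ca Sc Ti Cr Mn Fe Co Ni Cu Zn Ga Ge As Se
    Br Kr Rb Sr Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te Xe Cs Ba La Ce Pr Nd Pm
    Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr
    Ra Ac Th Pa Np Pu Am Cm Bk Cf Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh
    Fl Mc Lv Ts Og""".split()
)

#: Pairs like "Sc" that could equally read as two one-letter atoms
#: (sulfur + aromatic carbon).  Resolved greedily as the two-letter
#: element, with a logged warning.
_AMBIGUOUS_PAIRS = frozenset({"Sc", "Cn", "Cs", "Os", "In", "Sn", "No", "Nb"})


class InvalidSmilesError(ValueError):
    """A SMILES string the cheminformatics backend cannot parse.

    Carries the offending string so callers can skip and log it rather
    than abort a whole dataset.
    """

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


@dataclass(frozen=True)
class FingerprintConfig:
    """Bit count and maximum topological walk length of the fingerprint."""

    length: int = 1024
    max_walk: int = 7

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("fingerprint length must be positive")
        if self.max_walk < 1:
            raise ValueError("max_walk must be >= 1")


def fingerprint(
    smiles: str, config: FingerprintConfig = FingerprintConfig()
) -> np.ndarray:
    """Hashed topological-walk bit vector of a molecule.

    Deterministic: the same SMILES and configuration always yield the
    same bits.  Raises :class:`InvalidSmilesError` on unparseable input.
    """
    from rdkit import Chem  # deferred: RDKit import is slow

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    bv = Chem.RDKFingerprint(
        mol, minPath=1, maxPath=config.max_walk, fpSize=config.length
    )
    arr = np.zeros(config.length, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(
    smiles_list: list[str],
    config: FingerprintConfig = FingerprintConfig(),
    skip_invalid: bool = False,
) -> tuple[np.ndarray, list[int]]:
    """Stack fingerprints row-wise.

    With ``skip_invalid`` unparseable strings are dropped and logged;
    the second return value lists the kept row indices into the input.
    """
    rows, kept = [], []
    for i, s in enumerate(smiles_list):
        try:
            rows.append(fingerprint(s, config))
            kept.append(i)
        except InvalidSmilesError:
            if not skip_invalid:
                raise
            logger.warning("skipping unparseable SMILES at row %d: %r", i, s)
    return np.asarray(rows, dtype=np.uint8), kept


# -- tokenisation --------------------------------------------------------


def tokenize_chars(smiles: str) -> list[str]:
    """One token per character, in order."""
    return list(smiles)


def tokenize_atoms(smiles: str) -> list[str]:
    """Character tokens with two-letter element symbols merged.

    Greedy left-to-right: an uppercase+lowercase pair that names an
    element (inside or outside bracket atoms) becomes a single token;
    everything else — bonds, branches, ring-closure digits, ``%``,
    brackets, charges, stereo marks, aromatic lowercase atoms — is a
    single-character token.  Total: any string tokenises.
    """
    tokens: list[str] = []
    i = 0
    while i < len(smiles):
        pair = smiles[i : i + 2]
        if len(pair) == 2 and pair in TWO_LETTER_ELEMENTS:
            if pair in _AMBIGUOUS_PAIRS:
                logger.warning(
                    "ambiguous pair %r at position %d of %r grouped as the "
                    "two-letter element",
                    pair,
                    i,
                    smiles,
                )
            tokens.append(pair)
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


@dataclass
class Vocabulary:
    """Token -> integer index map for the embedding layer.

    Indices 0 (padding) and 1 (unknown token) are reserved; real tokens
    are numbered contiguously from 2 in first-occurrence order.
    """

    index: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.index)

    @property
    def size(self) -> int:
        """Total index count including the two reserved slots."""
        return len(self.index) + 2

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, UNK_INDEX)


def build_vocab(sequences: list[list[str]]) -> Vocabulary:
    """Index every distinct token, in first-occurrence order, from 2 up."""
    if not sequences:
        raise ValueError("cannot build a vocabulary from an empty collection")
    index: dict[str, int] = {}
    for seq in sequences:
        for token in seq:
            if token not in index:
                index[token] = len(index) + 2
    return Vocabulary(index=index)


def encode_sequence(
    seq: list[str], vocab: Vocabulary, pad_to: int | None = None
) -> np.ndarray:
    """Map tokens through the vocabulary; unseen tokens become 1.

    With ``pad_to`` the result is right-padded with 0 to that length;
    sequences longer than ``pad_to`` are rejected.
    """
    ids = [vocab[token] for token in seq]
    if pad_to is not None:
        if len(ids) > pad_to:
            raise ValueError(
                f"sequence of length {len(ids)} exceeds pad_to={pad_to}"
            )
        ids = ids + [PAD_INDEX] * (pad_to - len(ids))
    return np.asarray(ids, dtype=np.int64)


def encode_matrix(
    sequences: list[list[str]], vocab: Vocabulary, pad_to: int | None = None
) -> np.ndarray:
    """Encode and pad a batch of sequences into one integer matrix."""
    if pad_to is None:
        pad_to = max((len(s) for s in sequences), default=0)
    return np.stack([encode_sequence(s, vocab, pad_to) for s in sequences])
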