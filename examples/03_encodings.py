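"""Encode a molecule three ways: fingerprint, character and atom tokens.

Uses benzoyl chloride to show the difference between character-wise
tokenisation and atom-grouped tokenisation (Cl as one token), plus the
1024-bit topological fingerprint used by the classical classifiers.
"""

from chemont import build_vocab, encode_sequence, fingerprint, tokenize_atoms, tokenize_chars

smiles = "ClC(=O)C1=CC=CC=C1"  # benzoyl chloride

chars = tokenize_chars(smiles)
atoms = tokenize_atoms(smiles)
print(f"SMILES: {smiles}")
print(f"character tokens ({len(chars)}): {chars}")
print(f"atom-grouped tokens ({len(atoms)}): {atoms}")
# The counts differ by one because chlorine is two characters but a
# single atom token; ring-closure digits stay separate in both modes.

vocab = build_vocab([atoms])
ids = encode_sequence(atoms, vocab, pad_to=20)
print(f"integer encoding (pad 0, unknown 1): {ids.tolist()}")

fp = fingerprint(smiles)
print(f"fingerprint: {fp.size} bits, {int(fp.sum())} set")
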