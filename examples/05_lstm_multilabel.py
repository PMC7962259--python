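"""Train the multi-label LSTM on tokenised SMILES and inspect abstention.

Builds a 5-class x 100-member motif fixture, trains the
embedding -> LSTM -> dense -> dropout -> sigmoid network for 20 epochs
with binary cross-entropy, and reports held-out macro-F1, the
per-molecule F1 mean, and how many molecules the network abstained on
(no class score above 0.5).
"""

from chemont import (
    DatasetSpec,
    FixtureSpec,
    NetworkConfig,
    build_vocab,
    encode_matrix,
    make_label_matrix,
    make_toy_ontology,
    predict_classes,
    predict_scores,
    score_multi_label,
    select_balanced,
    split,
    tokenize_atoms,
    train_network,
)

ontology = make_toy_ontology(FixtureSpec(n_classes=5, members_per_class=100, seed=4))
dataset = select_balanced(ontology, DatasetSpec(5, 100, seed=4))
parts = split(dataset, (0.7, 0.1, 0.2), seed=4)
classes = sorted(dataset.assignments)

seqs = {p: [tokenize_atoms(r.smiles) for r in parts.partition(p)]
        for p in ("train", "validation", "test")}
vocab = build_vocab(seqs["train"])
pad = max(len(s) for part in seqs.values() for s in part)
X = {p: encode_matrix(seqs[p], vocab, pad) for p in seqs}
Y = {p: make_label_matrix([r.class_id for r in parts.partition(p)], classes)
     for p in seqs}

config = NetworkConfig(epochs=20, seed=0)
network, history = train_network(
    config, (X["train"], Y["train"]), (X["validation"], Y["validation"]),
    class_labels=classes,
)
print(f"epochs: {len(history)}, final train loss {history.train_loss[-1]:.4f}, "
      f"final validation loss {history.val_loss[-1]:.4f}")

scores = predict_scores(network, X["test"])
pred_sets = predict_classes(scores, config.threshold, classes)
truth = {r.member_id: {r.class_id} for r in parts.test}
pred_map = {r.member_id: p for r, p in zip(parts.test, pred_sets)}
report = score_multi_label(pred_map, truth, classes)

per_mol = sum(report.per_molecule_f1.values()) / len(report.per_molecule_f1)
print(f"held-out macro-F1 = {report.macro_f1:.3f}, per-molecule F1 mean = {per_mol:.3f}")
print(f"abstentions: {len(report.abstentions)} of {len(parts.test)} test molecules")
# Unlike the classical classifiers the network can return an empty set;
# abstentions are listed rather than forced into a wrong single guess.
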