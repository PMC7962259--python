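# chemont

Machine learning for **structure-based chemical ontology
classification**: given a molecule's structure (as a SMILES string),
predict which class of a chemical ontology it belongs to.

Chemical ontologies such as ChEBI organise molecular entities beneath a
subsumption (`is_a`) hierarchy, but they are curated by hand and cannot
keep pace with the tens of millions of structures in public databases.
`chemont` provides the machinery to study how well adaptive classifiers
can take over part of that work:

* **ontology handling** — parse an OBO export into a subsumption DAG,
  keep only `is_a` edges and non-obsolete terms, and distinguish
  *classes* from *leaf members* (leaves with a SMILES annotation — the
  classification instances);
* **balanced sampling** — build an N×M problem (N classes, exactly M
  members each) with a smallest-first, non-overlapping selection
  strategy, so that no molecule is assigned to two classes and the
  train/validation/test split stays clean;
* **encodings** — 1024-bit topological path fingerprints (RDKit) for
  fixed-length input, and lossless SMILES tokenisation, character-wise
  or with two-letter element symbols (Cl, Br, ...) grouped into single
  tokens;
* **classifiers** — eight classical algorithms (one-vs-rest logistic
  regression, KNN, decision tree, random forest, naive Bayes, LDA, and
  SVMs with linear/RBF/sigmoid kernels) emitting one class per
  molecule, and a multi-label **LSTM** (embedding → LSTM → dense →
  dropout → per-class sigmoid, binary cross-entropy) that can predict
  several classes or *abstain* entirely — implemented directly in
  NumPy with verified gradients;
* **evaluation** — per-class precision/recall/F1
  (P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R)), per-molecule F1
  and abstention reporting, and an ontology-aware **path-length
  metric**: the number of subsumption edges between each predicted and
  each asserted parent class (0 = exact match), with redundant
  superclass predictions condensed away first;
* **synthetic fixtures** — toy ontologies whose leaves carry SMILES
  with class-specific structural motifs, so the whole pipeline is
  testable offline, without downloading any ontology.

Everything is seeded and bit-reproducible: the same configuration
yields byte-identical datasets and identical predictions.

## Worked example

`examples/` contains one short script per capability. For instance,
tokenising benzoyl chloride (`examples/03_encodings.py`):

```
SMILES: ClC(=O)C1=CC=CC=C1
character tokens (18): ['C', 'l', 'C', '(', '=', 'O', ')', 'C', '1', '=', 'C', 'C', '=', 'C', 'C', '=', 'C', '1']
atom-grouped tokens (17): ['Cl', 'C', '(', '=', 'O', ')', 'C', '1', '=', 'C', 'C', '=', 'C', 'C', '=', 'C', '1']
integer encoding (pad 0, unknown 1): [2, 3, 4, 5, 6, 7, 3, 8, 5, 3, 3, 5, 3, 3, 5, 3, 8, 0, 0, 0]
fingerprint: 1024 bits, 103 set
```

The two tokenisations differ only in chlorine: two characters versus
one atom token. Training the LSTM on a 5-class × 100-member motif
fixture (`examples/05_lstm_multilabel.py`) prints:

```
epochs: 20, final train loss 0.0002, final validation loss 0.0001
held-out macro-F1 = 1.000, per-molecule F1 mean = 1.000
abstentions: 0 of 100 test molecules
```

i.e. the network learns the class-defining substructures perfectly on
this separable toy and never has to abstain — on real ontology data
abstention is precisely the behaviour to watch. The ontology-aware
scoring (`examples/06_path_length_evaluation.py`) shows the path
metric: an exact match contributes 0, a sibling prediction 2, and a
prediction accompanied by its own superclass is condensed before
counting:

```
m3 condensed from ['acid', 'carboxylic'] to ['carboxylic']
mean path length = 0.667 (0 would be all exact matches)
mean parent count = 1.000
```

## Command line

The staged pipeline is also available as a thin CLI over the library —
`sample`, `encode`, `train`, `evaluate`, or `all`, each taking one JSON
config file and writing its artifact plus a provenance record:

```sh
chemont all config.json
```

See `chemont --help` and the module docstring of `chemont/cli.py` for
the config keys.

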