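# Methods

## The classification problem

Chemical ontologies such as ChEBI organise molecular entities under a
subsumption (`is_a`) hierarchy. Terms split into two roles for learning:

* **leaf members** — terms with no children that carry a SMILES
  annotation, i.e. fully defined molecular structures; these are the
  instances to classify;
* **classes** — terms subsuming at least two leaf members anywhere in
  their descendant closure; these are the prediction targets.

The task is: given a molecule's structure, predict the ontology class
(or classes) it belongs to. `chemont` builds balanced supervised
problems from such an ontology and evaluates two families of learners
on them.

## Balanced non-overlapping sampling

Real chemical ontologies are diamond-shaped: a leaf typically sits
below many overlapping classes, and class sizes span orders of
magnitude. `select_balanced` therefore draws an *N x M* problem — N
classes with exactly M members each — under a global disjointness
constraint: no leaf is assigned to more than one class, so the later
train/validation/test split is clean.

Candidate classes are processed in ascending order of leaf-member
count (ties break by ascending term id, for determinism). A class is
filled when at least M of its leaf members are still unused — M are
then drawn uniformly at random without replacement — and skipped
otherwise; iteration stops after N classes and raises an error naming
the number of fillable classes when N cannot be reached. Smallest-first
ordering matters: small classes are the ones whose members are most
likely to also lie beneath a larger class, so filling them first
minimises the distortion the disjointness constraint introduces.
Members are drawn from the class's full descendant leaf closure, not
only its direct children, and no chemical-diversity weighting is
applied.

Splitting is stratified by class with largest-remainder apportionment,
so per-class partition sizes deviate from the exact proportions by at
most one record. The default fractions are (0.7, 0.1, 0.2); a zero
validation fraction gives the two-way split used for classifiers
without hyper-parameters. With 500 classes x 100 members this puts
exactly 10,000 of 50,000 records in the test partition.

## Input encodings

* **Fingerprints** (`fingerprint`) — RDKit's path-based
  `RDKFingerprint`, 1024 bits, walks of length 1–7 (the backend's
  default maximum). Unparseable SMILES raise a structured error
  carrying the offending string, so callers can skip and log rather
  than abort.
* **Character tokens** (`tokenize_chars`) — one token per character.
* **Atom-grouped tokens** (`tokenize_atoms`) — identical except that
  an uppercase+lowercase pair naming a periodic-table element (Cl, Br,
  Si, Na, ...) becomes one token, inside or outside bracket atoms.
  Ring-closure digits, including multi-digit `%nn` pointers, stay as
  separate digit tokens because they are unbounded and would explode a
  token vocabulary. Ambiguous pairs such as `Sc` (scandium vs
  sulfur + aromatic carbon) are resolved greedily as the two-letter
  element with a logged warning; SMILES that genuinely contain such
  juxtapositions are rare, and greedy resolution keeps tokenisation
  total and deterministic. Both modes are lossless: concatenating the
  tokens reproduces the input exactly.

Token sequences are mapped to integers through a `Vocabulary` with
reserved indices 0 (padding) and 1 (unknown token); unknown tokens at
inference must not crash the model, hence the explicit fallback index.

## Classifiers

Classical algorithms (logistic regression with an explicit one-vs-rest
wrapper, k-nearest neighbours, decision tree, random forest, Gaussian
naive Bayes, linear discriminant analysis, and SVMs with linear, RBF
and sigmoid kernels) are delegated to scikit-learn behind a uniform
`ClassifierSpec`/`train_classical`/`predict_classical` surface. They
consume fingerprints and always emit exactly one label per molecule.
Hyper-parameters default to the library defaults; anything overridden
is recorded in the spec, and stochastic estimators are keyed to the
spec's seed. Naive Bayes is the Gaussian (diagonal-covariance) variant,
so its contrast with LDA isolates covariance treatment: on data with
independent, equal-covariance features the two agree, and their
divergence on fingerprints measures inter-bit correlation.

## The sequence network

The multi-label model is a recurrent network over token sequences:
token embedding → unidirectional LSTM → dense (ReLU) → dropout → dense
with per-class sigmoid outputs, trained with binary cross-entropy.
Each output unit is an independent membership score in [0, 1];
thresholding (default 0.5, strictly greater-than for determinism at
the boundary) yields a class set that may be empty — an *abstention*,
reported explicitly rather than forced into a guess — or contain
several classes.

The network is implemented directly in NumPy: a hand-written forward
pass, backpropagation through time, and Adam. Right-padded positions
are handled with a carry-forward mask (padded steps copy the recurrent
state), so the classifying hidden state is the one at each sequence's
true last token and padding length cannot affect outputs. Gradients
are verified against central finite differences in the test suite.

Defaults: embedding 64, LSTM 128, dense 128, dropout 0.2, Adam at
learning rate 5e-3, batch 32, 100 epochs, forget-gate bias initialised
to 1, Glorot-uniform weights. The learning rate and batch size were
fixed once on the development fixture (motif toys converge within
~20–30 epochs there) and are plain config fields. All initialisation
and shuffling derive from the config seed, so training is
bit-reproducible.

Label vectors are single-hot by default — the sampled class alone is
positive, since evaluation scores predictions against the class each
molecule was sampled from. `make_label_matrix(..., include_ancestors=True)`
provides the multi-hot ancestor-closure alternative for experiments
where superclass membership should be rewarded.

Training history records loss, micro-precision and micro-recall per
epoch: training metrics accumulate over the epoch's mini-batches (so
the first epochs mix pre- and post-update behaviour, as is
conventional), validation metrics come from a full forward pass at
epoch end. The history exists to expose overfitting — on real data
validation loss rebounds while thresholded precision/recall can keep
creeping up as scores drift toward the threshold without crossing it.

## Evaluation

Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean, with the zero-denominator convention "define as 0 and
flag" so macro averages stay total. Multi-label scoring adds a
per-molecule F1 (predicted set vs truth set) and the abstention set.

The ontology-aware metric compares predicted against asserted parent
classes by path length: for every molecule, every (asserted,
predicted) pair contributes the number of subsumption edges between
the two terms, 0 for an exact match. Distance is the shortest path in
the `is_a` graph treated as **undirected**: predictions can be
siblings or descendants of the asserted class, not only ancestors, and
the undirected convention is the one that is total over such sets
while agreeing with the upward worked examples (direct parent = 1).
Disconnected pairs get a no-path marker, are excluded from the mean
and counted separately. The overall mean weights each pair equally.
Prediction sets are *condensed* first — every class that is an
ancestor of another class in the set is dropped, leaving an antichain —
both before the path metric and before `mean_parent_count`, so a
prediction accompanied by its own superclasses counts once.

## Synthetic fixtures

`make_toy_ontology` generates the study conditions for every learning
test: a single-rooted DAG (root, optional intermediate levels, N
classes, M leaves per class) whose leaves carry SMILES with the class
identity encoded chemically — each class has a distinctive motif
(halogen, heteroatom, unsaturation or ring) grafted as a branch onto a
random backbone drawn from a small grammar of acyclic C/O/N chains
with an optional terminal ring. Validity is guaranteed by
construction; every generated string parses in RDKit. An
`overlap_fraction` attaches that share of leaves beneath a second
class, reproducing the diamond-shaped multiple inheritance that makes
the sampler's disjointness constraint binding.

What the fixtures do **not** emulate: realistic chemistry (motifs are
single features, not functional-class definitions), aromatic SMILES
notation, charged/bracket-atom species, stereochemistry, heavy class
imbalance, and deep multiple inheritance. Passing tests therefore show
the machinery is correct and that separable signal is learned — not
that any particular accuracy transfers to a real ontology, where
classes overlap chemically and class membership is not reducible to
one substructure.

## Problem sizes and numerical choices

Learning tests run at toy scale, chosen so the full suite and the
acceptance script each finish in minutes on one CPU: 10 classes x 50
members for the classical sanity check, 5 classes x 200 members and 30
epochs (best of up to 3 seeds) for the network, 100 fixture ontologies
x 5 seeds for sampler invariants, 200 random DAGs (<= 50 nodes) for the
path-metric oracle. Split fractions sum to 1 within 1e-9; argmax ties
in classical prediction resolve to the first label in sorted order;
cycles in an input ontology are rejected loudly rather than broken
silently; terms with multiple SMILES annotations use the first with a
warning.

## Known limitations

* The NumPy LSTM is single-threaded and loops over timesteps; it is
  sized for the balanced toy problems this package constructs, not for
  full-ontology training runs.
* Multi-digit ring closures and rare two-letter/one-letter token
  ambiguities mean atom-grouped tokenisation is heuristic, not a SMILES
  parser; it is deliberately total instead.
* The path metric's undirected-shortest-path convention for
  different-branch predictions is one defensible choice among several;
  no-path counts are reported so users can detect when it matters.
* Scoring against the sampled class treats the sampling selection as
  ground truth; with `path_length_report` the asserted direct parents
  can be used instead when they differ from the sampled classes.
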