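"""The NumPy LSTM: gradients, training behaviour, scoring and abstention."""

import numpy as np
import pytest

from chemont.encoding import build_vocab, encode_matrix, tokenize_atoms
from chemont.evaluation import score_multi_label
from chemont.fixtures import FixtureSpec, make_toy_ontology
from chemont.network import (
    NetworkConfig,
    _backward,
    _forward,
    _init_params,
    load_network,
    make_label_matrix,
    predict_classes,
    predict_scores,
    save_network,
    train_network,
)
from chemont.sampling import DatasetSpec, select_balanced, split


def tiny_problem(seed=0, n=40, t=9, vocab=7, classes=3):
    rng = np.random.default_rng(seed)
    X = rng.integers(1, vocab, size=(n, t))
    X[rng.random((n, t)) < 0.2] = 0  # irregular padding pattern
    X.sort(axis=1)  # not realistic but fine for shape tests
    y = np.zeros((n, classes))
    y[np.arange(n), rng.integers(classes, size=n)] = 1.0
    return X, y


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        cfg = NetworkConfig(
            embedding_dim=5, lstm_units=6, dense_units=4,
            dropout_rate=0.2, epochs=1, seed=0,
        )
        V, C, B, T = 9, 3, 4, 7
        params = _init_params(rng, V, cfg, C)
        ids = rng.integers(0, V, size=(B, T))
        ids[0, 5:] = 0
        ids[2, 3:] = 0
        y = (rng.random((B, C)) < 0.4).astype(float)
        drop = (rng.random((B, cfg.dense_units)) < 0.8) / 0.8
        scores, cache = _forward(params, ids, drop_mask=drop)
        grads = _backward(params, cache, scores, y)

        def loss():
            s, _ = _forward(params, ids, drop_mask=drop)
            p = np.clip(s, 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        eps = 1e-6
        for k in params:
            flat, gflat = params[k].reshape(-1), grads[k].reshape(-1)
            for i in rng.choice(flat.size, size=min(15, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(num, rel=5e-3, abs=1e-7)

    def test_padding_carries_state_forward(self):
        # appending pad tokens must not change the network output
        rng = np.random.default_rng(1)
        cfg = NetworkConfig(embedding_dim=4, lstm_units=5, dense_units=4, epochs=1)
        params = _init_params(rng, 6, cfg, 2)
        ids = rng.integers(1, 6, size=(3, 5))
        padded = np.hstack([ids, np.zeros((3, 4), dtype=int)])
        s1, _ = _forward(params, ids)
        s2, _ = _forward(params, padded)
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestTraining:
    def test_history_has_one_record_per_epoch(self):
        X, y = tiny_problem()
        cfg = NetworkConfig(
            embedding_dim=8, lstm_units=8, dense_units=8, epochs=4, seed=0
        )
        _, hist = train_network(cfg, (X, y), (X[:10], y[:10]))
        assert len(hist) == 4
        assert len(hist.val_loss) == 4

    def test_training_loss_decreases_early(self):
        X, y = tiny_problem(seed=3)
        cfg = NetworkConfig(
            embedding_dim=8, lstm_units=12, dense_units=8, epochs=6, seed=1
        )
        _, hist = train_network(cfg, (X, y))
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_label_dimension_mismatch_rejected(self):
        X, y = tiny_problem()
        with pytest.raises(ValueError, match="label dimension"):
            train_network(
                NetworkConfig(epochs=1),
                (X, y),
                (X[:5], np.zeros((5, y.shape[1] + 1))),
            )

    def test_deterministic_given_seed(self):
        X, y = tiny_problem(seed=5)
        cfg = NetworkConfig(embedding_dim=6, lstm_units=6, dense_units=6, epochs=2, seed=9)
        net1, _ = train_network(cfg, (X, y))
        net2, _ = train_network(cfg, (X, y))
        for k in net1.params:
            np.testing.assert_array_equal(net1.params[k], net2.params[k])


@pytest.fixture(scope="module")
def trained():
    X, y = tiny_problem(seed=7)
    cfg = NetworkConfig(embedding_dim=8, lstm_units=8, dense_units=8, epochs=3, seed=2)
    net, _ = train_network(cfg, (X, y), class_labels=["a", "b", "c"])
    return net, X


class TestScoring:
    def test_scores_in_unit_interval_one_per_input(self, trained):
        net, X = trained
        scores = predict_scores(net, X)
        assert scores.shape == (len(X), 3)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_inference_deterministic(self, trained):
        net, X = trained
        np.testing.assert_array_equal(predict_scores(net, X), predict_scores(net, X))

    def test_mislength_input_rejected(self, trained):
        net, X = trained
        with pytest.raises(ValueError, match="padded"):
            predict_scores(net, X[:, :-2])

    def test_checkpoint_round_trip(self, trained, tmp_path):
        net, X = trained
        path = tmp_path / "net.npz"
        save_network(net, path)
        loaded = load_network(path)
        np.testing.assert_array_equal(predict_scores(loaded, X), predict_scores(net, X))
        assert loaded.class_labels == net.class_labels


class TestPredictClasses:
    def test_above_threshold_selected(self):
        assert predict_classes(np.array([0.6, 0.4]), 0.5, ["c1", "c2"]) == {"c1"}

    def test_all_below_threshold_is_abstention(self):
        assert predict_classes(np.array([0.2, 0.4]), 0.5) == set()

    def test_exact_threshold_excluded(self):
        assert predict_classes(np.array([0.5, 0.7]), 0.5, ["a", "b"]) == {"b"}

    def test_matrix_input_gives_list_of_sets(self):
        out = predict_classes(np.array([[0.9, 0.1], [0.1, 0.1]]), 0.5, ["a", "b"])
        assert out == [{"a"}, set()]


class TestLabelMatrix:
    def test_single_hot_default(self):
        y = make_label_matrix(["B", "A"], ["A", "B"])
        np.testing.assert_array_equal(y, [[0, 1], [1, 0]])

    def test_ancestor_closure_mode(self, chain_graph):
        y = make_label_matrix(
            ["C"], ["A", "B", "C"], graph=chain_graph, include_ancestors=True
        )
        np.testing.assert_array_equal(y, [[1, 1, 1]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            make_label_matrix(["Z"], ["A"])


def motif_problem(n_classes, members, seed, mode=tokenize_atoms):
    ont = make_toy_ontology(FixtureSpec(n_classes=n_classes, members_per_class=members, seed=seed))
    ds = select_balanced(ont, DatasetSpec(n_classes, members, seed=seed))
    parts = split(ds, (0.7, 0.1, 0.2), seed=seed)
    classes = sorted(ds.assignments)
    seqs = {p: [mode(r.smiles) for r in parts.partition(p)] for p in ("train", "validation", "test")}
    vocab = build_vocab(seqs["train"])
    pad = max(len(s) for part in seqs.values() for s in part)
    X = {p: encode_matrix(seqs[p], vocab, pad) for p in seqs}
    Y = {p: make_label_matrix([r.class_id for r in parts.partition(p)], classes) for p in seqs}
    return parts, classes, X, Y


@pytest.fixture(scope="module")
def fitted():
    parts, classes, X, Y = motif_problem(3, 60, seed=13)
    cfg = NetworkConfig(
        embedding_dim=16, lstm_units=24, dense_units=24,
        epochs=15, seed=0,
    )
    net, hist = train_network(
        cfg, (X["train"], Y["train"]), (X["validation"], Y["validation"]),
        class_labels=classes,
    )
    return parts, classes, X, net, hist


class TestMotifLearning:
    """Held-out behaviour on a motif-separable toy, kept small for speed."""

    def test_heldout_macro_f1_high(self, fitted):
        parts, classes, X, net, _ = fitted
        preds = predict_classes(predict_scores(net, X["test"]), 0.5, classes)
        truth = {r.member_id: {r.class_id} for r in parts.test}
        pred_map = {r.member_id: p for r, p in zip(parts.test, preds)}
        rep = score_multi_label(pred_map, truth, classes)
        assert rep.macro_f1 >= 0.8

    def test_most_molecules_get_at_least_one_class(self, fitted):
        parts, classes, X, net, _ = fitted
        preds = predict_classes(predict_scores(net, X["test"]), 0.5, classes)
        with_prediction = sum(1 for p in preds if p)
        assert with_prediction >= 0.9 * len(preds)

    def test_char_and_atom_tokenisation_comparable(self):
        # encoding granularity should not change what is learnable
        from chemont.encoding import tokenize_chars

        f1s = {}
        for name, mode in (("atoms", tokenize_atoms), ("chars", tokenize_chars)):
            parts, classes, X, Y = motif_problem(3, 100, seed=29, mode=mode)
            cfg = NetworkConfig(
                embedding_dim=16, lstm_units=24, dense_units=24, epochs=20, seed=1
            )
            net, _ = train_network(cfg, (X["train"], Y["train"]), class_labels=classes)
            preds = predict_classes(predict_scores(net, X["test"]), 0.5, classes)
            truth = {r.member_id: {r.class_id} for r in parts.test}
            pred_map = {r.member_id: p for r, p in zip(parts.test, preds)}
            f1s[name] = score_multi_label(pred_map, truth, classes).macro_f1
        assert abs(f1s["atoms"] - f1s["chars"]) <= 0.1
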