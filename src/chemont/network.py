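"""Multi-label recurrent classifier over SMILES token sequences.

Architecture: token embedding -> unidirectional LSTM (final hidden
state) -> dense (ReLU) -> dropout -> dense with per-class sigmoid
outputs.  Training minimises binary cross-entropy with Adam, so each
output unit learns an independent membership score in [0, 1]; at
prediction time scores are thresholded (default 0.5, strict) into a
class set that may be empty — an *abstention* — or contain several
classes.

The network is implemented directly on NumPy arrays: a hand-written
forward pass, backpropagation through time with a carry-forward mask
over right-padded positions (padded steps copy the recurrent state, so
the final hidden state is the one at each sequence's true last token),
and an Adam update.  Gradients are verified against finite differences
in the test suite.  All weight initialisation and shuffling derive from
the config seed, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .encoding import PAD_INDEX

__all__ = [
    "NetworkConfig",
    "TrainingHistory",
    "SequenceNetwork",
    "make_label_matrix",
    "train_network",
    "predict_scores",
    "predict_classes",
    "save_network",
    "load_network",
]

_EPS = 1e-7


@dataclass(frozen=True)
class NetworkConfig:
    """Layer sizes, regularisation and optimisation settings.

    ``threshold`` is the class-membership cut-off applied to the sigmoid
    scores (strictly greater-than).  ``epochs`` defaults to 100 — long
    enough for validation loss to rebound on real data, which is the
    overfitting diagnostic the history exists to expose — but toy
    problems converge far sooner.
    """

    embedding_dim: int = 64
    lstm_units: int = 128
    dense_units: int = 128
    dropout_rate: float = 0.2
    epochs: int = 100
    threshold: float = 0.5
    seed: int = 0
    learning_rate: float = 0.005
    batch_size: int = 32

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie strictly between 0 and 1")
        for name in ("embedding_dim", "lstm_units", "dense_units", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class TrainingHistory:
    """Per-epoch loss / precision / recall on training and validation data.

    Training metrics are accumulated over the epoch's mini-batches;
    validation metrics come from one full forward pass at epoch end
    (empty when no validation set was supplied).  Micro-averaged
    precision/recall at the config threshold.
    """

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_precision: list[float] = field(default_factory=list)
    train_recall: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_precision: list[float] = field(default_factory=list)
    val_recall: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)

    def to_csv(self, path: str | Path) -> None:
        """Columns: epoch, split, loss, precision, recall."""
        with open(path, "w") as fh:
            fh.write("epoch,split,loss,precision,recall\n")
            for i, e in enumerate(self.epochs):
                fh.write(
                    f"{e},train,{self.train_loss[i]},"
                    f"{self.train_precision[i]},{self.train_recall[i]}\n"
                )
                if self.val_loss:
                    fh.write(
                        f"{e},validation,{self.val_loss[i]},"
                        f"{self.val_precision[i]},{self.val_recall[i]}\n"
                    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


def _init_params(
    rng: np.random.Generator, vocab_size: int, config: NetworkConfig, n_classes: int
) -> dict[str, np.ndarray]:
    d, h, u = config.embedding_dim, config.lstm_units, config.dense_units
    params = {
        "emb": rng.normal(0.0, 0.05, size=(vocab_size, d)),
        "wx": _glorot(rng, (d, 4 * h)),
        "wh": _glorot(rng, (h, 4 * h)),
        "b": np.zeros(4 * h),
        "w1": _glorot(rng, (h, u)),
        "b1": np.zeros(u),
        "w2": _glorot(rng, (u, n_classes)),
        "b2": np.zeros(n_classes),
    }
    params["b"][h : 2 * h] = 1.0  # forget-gate bias: remember by default
    params["emb"][PAD_INDEX] = 0.0
    return params


def _forward(
    params: dict[str, np.ndarray],
    ids: np.ndarray,
    drop_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the network; returns (sigmoid scores, cache for backprop).

    ``drop_mask`` is the (already scaled) inverted-dropout mask for the
    dense layer, or None for inference.
    """
    h_units = params["wh"].shape[0]
    B, T = ids.shape
    h = np.zeros((B, h_units))
    c = np.zeros((B, h_units))
    mask = (ids != PAD_INDEX).astype(float)
    steps = []
    for t in range(T):
        x = params["emb"][ids[:, t]]
        z = x @ params["wx"] + h @ params["wh"] + params["b"]
        i = _sigmoid(z[:, :h_units])
        f = _sigmoid(z[:, h_units : 2 * h_units])
        g = np.tanh(z[:, 2 * h_units : 3 * h_units])
        o = _sigmoid(z[:, 3 * h_units :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        m = mask[:, t : t + 1]
        steps.append(
            {"x": x, "h_prev": h, "c_prev": c, "i": i, "f": f, "g": g, "o": o,
             "c_new": c_new, "m": m}
        )
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
    a1 = h @ params["w1"] + params["b1"]
    r1 = np.maximum(a1, 0.0)
    d1 = r1 * drop_mask if drop_mask is not None else r1
    logits = d1 @ params["w2"] + params["b2"]
    scores = _sigmoid(logits)
    cache = {"steps": steps, "h_final": h, "a1": a1, "r1": r1, "d1": d1,
             "drop_mask": drop_mask, "ids": ids}
    return scores, cache


def _bce(scores: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(scores, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _backward(
    params: dict[str, np.ndarray],
    cache: dict,
    scores: np.ndarray,
    y: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of mean binary cross-entropy w.r.t. every parameter."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    B, C = scores.shape
    h_units = params["wh"].shape[0]
    dlogits = (scores - y) / (B * C)  # sigmoid + BCE combined
    grads["w2"] = cache["d1"].T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    dd1 = dlogits @ params["w2"].T
    if cache["drop_mask"] is not None:
        dd1 = dd1 * cache["drop_mask"]
    da1 = dd1 * (cache["a1"] > 0)
    grads["w1"] = cache["h_final"].T @ da1
    grads["b1"] = da1.sum(axis=0)
    dh = da1 @ params["w1"].T
    dc = np.zeros((B, h_units))
    for t in range(len(cache["steps"]) - 1, -1, -1):
        step = cache["steps"][t]
        m = step["m"]
        dh_new = m * dh
        dc_new = m * dc
        dh_carry = (1.0 - m) * dh
        dc_carry = (1.0 - m) * dc
        tanh_c = np.tanh(step["c_new"])
        do = dh_new * tanh_c
        dcn = dc_new + dh_new * step["o"] * (1.0 - tanh_c**2)
        di = dcn * step["g"]
        df = dcn * step["c_prev"]
        dg = dcn * step["i"]
        dc = dcn * step["f"] + dc_carry
        i, f, g, o = step["i"], step["f"], step["g"], step["o"]
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        grads["wx"] += step["x"].T @ dz
        grads["wh"] += step["h_prev"].T @ dz
        grads["b"] += dz.sum(axis=0)
        dx = dz @ params["wx"].T
        np.add.at(grads["emb"], cache["ids"][:, t], dx)
        dh = dz @ params["wh"].T + dh_carry
    grads["emb"][PAD_INDEX] = 0.0  # the padding row stays pinned at zero
    return grads


@dataclass
class SequenceNetwork:
    """A trained network: parameters plus the shapes it was trained with."""

    config: NetworkConfig
    params: dict[str, np.ndarray]
    vocab_size: int
    n_classes: int
    seq_len: int
    class_labels: list[str] | None = None


def make_label_matrix(
    class_ids: list[str],
    classes: list[str],
    graph=None,
    include_ancestors: bool = False,
) -> np.ndarray:
    """Binary label matrix for the sigmoid outputs.

    Default is single-hot: the sampled class alone is positive, since
    predictions are scored against the class each molecule was sampled
    from.  With ``include_ancestors`` (requires ``graph``) every
    ancestor of the sampled class that is itself in ``classes`` is also
    marked positive — the multi-hot alternative for experiments where
    superclass membership should be rewarded.
    """
    index = {c: j for j, c in enumerate(classes)}
    y = np.zeros((len(class_ids), len(classes)))
    for i, cid in enumerate(class_ids):
        if cid not in index:
            raise ValueError(f"label {cid!r} not in the class list")
        y[i, index[cid]] = 1.0
        if include_ancestors:
            if graph is None:
                raise ValueError("include_ancestors requires the ontology graph")
            for anc in graph.ancestors(cid):
                if anc in index:
                    y[i, index[anc]] = 1.0
    return y


def _micro_counts(scores: np.ndarray, y: np.ndarray, threshold: float):
    pred = scores > threshold
    true = y > 0.5
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    return tp, fp, fn


def train_network(
    config: NetworkConfig,
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    class_labels: list[str] | None = None,
) -> tuple[SequenceNetwork, TrainingHistory]:
    """Train the embedding->LSTM->dense->dropout->sigmoid network.

    ``train`` and ``validation`` are (integer sequence matrix, binary
    label matrix) pairs; all sequences must be padded to one common
    length and the label matrices must share their class dimension.
    Returns the fitted network and its per-epoch history (one record
    per epoch).
    """
    X, Y = np.asarray(train[0]), np.asarray(train[1], dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or len(X) != len(Y):
        raise ValueError("train sequences and labels must be matching 2-D arrays")
    if validation is not None:
        Xv, Yv = np.asarray(validation[0]), np.asarray(validation[1], dtype=float)
        if Xv.shape[1] != X.shape[1]:
            raise ValueError("validation sequences padded to a different length")
        if Yv.shape[1] != Y.shape[1]:
            raise ValueError(
                f"label dimension mismatch: train has {Y.shape[1]} classes, "
                f"validation has {Yv.shape[1]}"
            )
    if class_labels is not None and len(class_labels) != Y.shape[1]:
        raise ValueError("class_labels length must equal the label dimension")

    rng = np.random.default_rng(config.seed)
    vocab_size = int(X.max(initial=1)) + 1
    if validation is not None:
        vocab_size = max(vocab_size, int(Xv.max(initial=1)) + 1)
    n_classes = Y.shape[1]
    params = _init_params(rng, vocab_size, config, n_classes)
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = TrainingHistory()
    n = len(X)
    keep = 1.0 - config.dropout_rate
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        tp = fp = fn = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            drop = (rng.random((len(xb), config.dense_units)) < keep) / keep
            scores, cache = _forward(params, xb, drop_mask=drop)
            grads = _backward(params, cache, scores, yb)
            step += 1
            lr_t = config.learning_rate * (
                np.sqrt(1 - beta2**step) / (1 - beta1**step)
            )
            for k in params:
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                params[k] -= lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)
            params["emb"][PAD_INDEX] = 0.0
            batch_losses.append(_bce(scores, yb))
            btp, bfp, bfn = _micro_counts(scores, yb, config.threshold)
            tp, fp, fn = tp + btp, fp + bfp, fn + bfn
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.train_precision.append(tp / (tp + fp) if tp + fp else 0.0)
        history.train_recall.append(tp / (tp + fn) if tp + fn else 0.0)
        if validation is not None:
            vs, _ = _forward(params, Xv)
            history.val_loss.append(_bce(vs, Yv))
            vtp, vfp, vfn = _micro_counts(vs, Yv, config.threshold)
            history.val_precision.append(vtp / (vtp + vfp) if vtp + vfp else 0.0)
            history.val_recall.append(vtp / (vtp + vfn) if vtp + vfn else 0.0)

    net = SequenceNetwork(
        config=config,
        params=params,
        vocab_size=vocab_size,
        n_classes=n_classes,
        seq_len=X.shape[1],
        class_labels=list(class_labels) if class_labels else None,
    )
    return net, history


def predict_scores(net: SequenceNetwork, sequences: np.ndarray) -> np.ndarray:
    """Membership scores in [0, 1], one row per input sequence.

    Inference is deterministic (dropout disabled).  Sequences must be
    padded to the length the network was trained with.
    """
    X = np.asarray(sequences)
    if X.ndim != 2 or X.shape[1] != net.seq_len:
        raise ValueError(
            f"sequences must be padded to length {net.seq_len}, got shape {X.shape}"
        )
    if X.max(initial=0) >= net.vocab_size:
        raise ValueError(
            "sequence contains token indices outside the training vocabulary; "
            "encode with the training Vocabulary (unseen tokens map to 1)"
        )
    scores, _ = _forward(net.params, X)
    return scores


def predict_classes(
    scores: np.ndarray,
    threshold: float = 0.5,
    class_labels: list[str] | None = None,
) -> set | list[set]:
    """Threshold scores into class sets; empty set = abstention.

    Membership is strict (score > threshold).  Accepts one score vector
    or a matrix of them; labels default to positional indices.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    arr = np.asarray(scores)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    labels = class_labels if class_labels is not None else list(range(arr.shape[1]))
    out = [
        {labels[j] for j in np.nonzero(row > threshold)[0]} for row in arr
    ]
    return out[0] if single else out


def save_network(net: SequenceNetwork, path: str | Path) -> None:
    """Checkpoint the network (weights + config + labels) to one .npz file."""
    meta = {
        "config": asdict(net.config),
        "vocab_size": net.vocab_size,
        "n_classes": net.n_classes,
        "seq_len": net.seq_len,
        "class_labels": net.class_labels,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.params)


def load_network(path: str | Path) -> SequenceNetwork:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    params = {k: data[k] for k in data.files if k != "meta"}
    return SequenceNetwork(
        config=NetworkConfig(**meta["config"]),
        params=params,
        vocab_size=meta["vocab_size"],
        n_classes=meta["n_classes"],
        seq_len=meta["seq_len"],
        class_labels=meta["class_labels"],
    )
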