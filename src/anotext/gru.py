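"""Recurrent sentiment classifier: BiGRU -> GRU -> softmax, trained with Adam.

Architecture (two hidden layers):

* input: a sequence of 100-dimensional word vectors;
* first hidden layer: 5 bidirectional gated recurrent units — two
  sub-units of 5 states each, one reading the sequence forward and one
  backward, their states concatenated per position (10 values);
* second hidden layer: 5 unidirectional gated recurrent units consuming
  the concatenated sequence; its final state summarizes the document;
* output layer: dense + softmax over two classes mapped to {-1, +1}.

The binary output space follows the pre-training regime, where polarity
comes from user review scores: the network never emits the neutral class
(that class exists only for expert and dictionary labels).

GRU recurrence used throughout (and hand-unrolled by the test oracle)::

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)
    n_t = tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)
    h_t = (1 - z_t) * h_{t-1} + z_t * n_t

Training minimizes categorical cross-entropy (natural log, probabilities
clamped at 1e-12) with the Adam optimizer; the recorded default learning
rate 5e-6 is a fine-tuning rate — raise it (around 1e-3) for from-scratch
training on small corpora.  Sequences are batch-padded with zero vectors
under a length mask; no truncation.  Everything is plain numpy,
gradients are exact backpropagation through time, and all randomness
flows from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingTable, vectorize
from .textprep import RawDocument, TokenSequence, clean_and_tokenize

__all__ = [
    "RnnConfig",
    "TrainingExample",
    "Prediction",
    "LearningCurve",
    "SentimentGRU",
    "forward",
    "cce",
    "train",
    "predict_document",
    "save_model",
    "load_model",
    "CLASS_OF_INDEX",
]

EPS = 1e-12

#: output-index -> sentiment-class mapping (index 0 -> -1, index 1 -> +1)
CLASS_OF_INDEX = {0: -1, 1: 1}
INDEX_OF_CLASS = {-1: 0, 1: 1}


@dataclass(frozen=True)
class RnnConfig:
    """Hyperparameters of the classifier and its optimizer."""

    input_dim: int = 100
    bi_units: int = 5          # per direction in the bidirectional layer
    uni_units: int = 5
    n_classes: int = 2
    learning_rate: float = 5e-6
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_dim, self.bi_units, self.uni_units, self.n_classes) < 1:
            raise ValueError("unit counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        for beta in (self.beta1, self.beta2):
            if not 0.0 < beta < 1.0:
                raise ValueError("Adam betas must lie in (0, 1)")


@dataclass(frozen=True)
class TrainingExample:
    """A vectorized document and its class-index label."""

    vectors: np.ndarray  # (T, input_dim)
    label: int           # index in [0, n_classes)

    def one_hot(self, n_classes: int = 2) -> np.ndarray:
        if not 0 <= self.label < n_classes:
            raise ValueError(f"label {self.label} invalid for {n_classes} classes")
        target = np.zeros(n_classes)
        target[self.label] = 1.0
        return target


@dataclass(frozen=True)
class Prediction:
    doc_id: str
    klass: int          # in {-1, +1}
    probability: float  # maximal class probability

    def to_dict(self) -> dict:
        return {"doc_id": self.doc_id, "class": self.klass,
                "probability": self.probability}


@dataclass
class LearningCurve:
    """Per-epoch training and validation cross-entropy."""

    train: list[float] = field(default_factory=list)
    validation: list[float] = field(default_factory=list)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _gru_param_names(prefix: str) -> list[str]:
    return [f"{prefix}_{g}" for g in ("Wz", "Wr", "Wh", "Uz", "Ur", "Uh",
                                      "bz", "br", "bh")]


class SentimentGRU:
    """Weight container for the BiGRU -> GRU -> dense classifier."""

    def __init__(self, config: RnnConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params()

    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params: dict[str, np.ndarray] = {}
        for prefix, d_in, units in (
            ("f", cfg.input_dim, cfg.bi_units),    # forward sub-unit
            ("b", cfg.input_dim, cfg.bi_units),    # backward sub-unit
            ("u", 2 * cfg.bi_units, cfg.uni_units)  # second hidden layer
        ):
            for gate in ("z", "r", "h"):
                params[f"{prefix}_W{gate}"] = _glorot(rng, d_in, units)
                params[f"{prefix}_U{gate}"] = _glorot(rng, units, units)
                params[f"{prefix}_b{gate}"] = np.zeros(units)
        params["out_W"] = _glorot(rng, cfg.uni_units, cfg.n_classes)
        params["out_b"] = np.zeros(cfg.n_classes)
        return params

    def copy(self) -> "SentimentGRU":
        return SentimentGRU(self.config, {k: v.copy() for k, v in self.params.items()})


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _gru_layer_forward(params: dict, prefix: str, X: np.ndarray,
                       mask: np.ndarray) -> tuple[np.ndarray, list]:
    """Run a GRU over a padded batch.

    X: (B, T, d); mask: (B, T) with 1 for valid steps.  At masked steps the
    state is carried unchanged, so the state at T-1 is the state at each
    sequence's last valid token.  Returns the state sequence (B, T, H) and
    the caches needed for backpropagation.
    """
    Wz, Wr, Wh = (params[f"{prefix}_{n}"] for n in ("Wz", "Wr", "Wh"))
    Uz, Ur, Uh = (params[f"{prefix}_{n}"] for n in ("Uz", "Ur", "Uh"))
    bz, br, bh = (params[f"{prefix}_{n}"] for n in ("bz", "br", "bh"))
    B, T, _ = X.shape
    H = Wz.shape[1]
    h = np.zeros((B, H))
    out = np.zeros((B, T, H))
    caches = []
    for t in range(T):
        x_t = X[:, t, :]
        m = mask[:, t][:, None]
        z = _sigmoid(x_t @ Wz + h @ Uz + bz)
        r = _sigmoid(x_t @ Wr + h @ Ur + br)
        n = np.tanh(x_t @ Wh + (r * h) @ Uh + bh)
        h_tilde = (1.0 - z) * h + z * n
        h_new = m * h_tilde + (1.0 - m) * h
        caches.append((x_t, h, z, r, n, m))
        h = h_new
        out[:, t, :] = h
    return out, caches


def _gru_layer_backward(params: dict, prefix: str, caches: list,
                        dOut_seq: np.ndarray | None,
                        dH_final: np.ndarray | None,
                        grads: dict) -> np.ndarray:
    """Backpropagate through one GRU layer.

    ``dOut_seq`` (B, T, H) carries per-step gradients of the state sequence
    (used when a higher layer consumed every position); ``dH_final`` (B, H)
    the gradient of the last state.  Returns dX (B, T, d) and accumulates
    parameter gradients into ``grads``.
    """
    Wz, Wr, Wh = (params[f"{prefix}_{n}"] for n in ("Wz", "Wr", "Wh"))
    Uz, Ur, Uh = (params[f"{prefix}_{n}"] for n in ("Uz", "Ur", "Uh"))
    T = len(caches)
    B, H = caches[0][1].shape
    d_in = Wz.shape[0]
    dX = np.zeros((B, T, d_in))
    dh = np.zeros((B, H)) if dH_final is None else dH_final.copy()
    for name in _gru_param_names(prefix):
        grads.setdefault(name, np.zeros_like(params[name]))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, z, r, n, m = caches[t]
        if dOut_seq is not None:
            dh = dh + dOut_seq[:, t, :]
        dh_tilde = dh * m
        dh_prev = dh * (1.0 - m)
        dz = dh_tilde * (n - h_prev)
        dn = dh_tilde * z
        dh_prev += dh_tilde * (1.0 - z)
        dan = dn * (1.0 - n * n)
        drh = dan @ Uh.T          # gradient of (r * h_prev)
        dr = drh * h_prev
        dh_prev += drh * r
        daz = dz * z * (1.0 - z)
        dar = dr * r * (1.0 - r)
        grads[f"{prefix}_Wz"] += x_t.T @ daz
        grads[f"{prefix}_Wr"] += x_t.T @ dar
        grads[f"{prefix}_Wh"] += x_t.T @ dan
        grads[f"{prefix}_Uz"] += h_prev.T @ daz
        grads[f"{prefix}_Ur"] += h_prev.T @ dar
        grads[f"{prefix}_Uh"] += (r * h_prev).T @ dan
        grads[f"{prefix}_bz"] += daz.sum(axis=0)
        grads[f"{prefix}_br"] += dar.sum(axis=0)
        grads[f"{prefix}_bh"] += dan.sum(axis=0)
        dX[:, t, :] = daz @ Wz.T + dar @ Wr.T + dan @ Wh.T
        dh_prev += daz @ Uz.T + dar @ Ur.T
        dh = dh_prev
    return dX


def _reverse_within_lengths(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's first ``lengths[b]`` positions, leaving padding."""
    out = np.zeros_like(X)
    for b, L in enumerate(lengths):
        if L:
            out[b, :L] = X[b, L - 1::-1]
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=-1, keepdims=True)


def _forward_batch(model: SentimentGRU, X: np.ndarray, mask: np.ndarray,
                   with_cache: bool = False):
    """Probabilities (B, n_classes) for a padded batch; optionally caches."""
    lengths = mask.sum(axis=1).astype(int)
    Xrev = _reverse_within_lengths(X, lengths)
    Hf, cache_f = _gru_layer_forward(model.params, "f", X, mask)
    Hb_rev, cache_b = _gru_layer_forward(model.params, "b", Xrev, mask)
    Hb = _reverse_within_lengths(Hb_rev, lengths)
    Y = np.concatenate([Hf, Hb], axis=2)          # (B, T, 2*bi_units)
    Y = Y * mask[:, :, None]                      # padded positions are zero
    H2, cache_u = _gru_layer_forward(model.params, "u", Y, mask)
    final = H2[:, -1, :] if X.shape[1] else np.zeros((X.shape[0], model.config.uni_units))
    logits = final @ model.params["out_W"] + model.params["out_b"]
    probs = _softmax(logits)
    if not with_cache:
        return probs
    return probs, (lengths, cache_f, cache_b, cache_u, final)


def _backward_batch(model: SentimentGRU, X: np.ndarray, mask: np.ndarray,
                    probs: np.ndarray, targets: np.ndarray, cache) -> dict:
    """Gradients of the mean CCE of the batch with respect to all weights."""
    lengths, cache_f, cache_b, cache_u, final = cache
    B = X.shape[0]
    grads: dict[str, np.ndarray] = {}
    dlogits = (probs - targets) / B
    grads["out_W"] = final.T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dfinal = dlogits @ model.params["out_W"].T
    dY = _gru_layer_backward(model.params, "u", cache_u, None, dfinal, grads)
    dY = dY * mask[:, :, None]
    Hn = model.config.bi_units
    dHf = dY[:, :, :Hn]
    dHb = dY[:, :, Hn:]
    dHb_rev = _reverse_within_lengths(dHb, lengths)
    dXf = _gru_layer_backward(model.params, "f", cache_f, dHf, None, grads)
    dXrev = _gru_layer_backward(model.params, "b", cache_b, dHb_rev, None, grads)
    dXb = _reverse_within_lengths(dXrev, lengths)
    _ = dXf + dXb  # input gradient, unused (embeddings are fixed)
    return grads


def forward(model: SentimentGRU, vecs: Sequence[np.ndarray]) -> np.ndarray:
    """Class-probability vector for one sequence of input vectors."""
    d = model.config.input_dim
    for v in vecs:
        if np.shape(v) != (d,):
            raise ValueError(f"input vector of shape {np.shape(v)}, expected ({d},)")
    T = len(vecs)
    X = np.asarray(vecs, dtype=float).reshape(1, T, d)
    mask = np.ones((1, T))
    return _forward_batch(model, X, mask)[0]


def cce(prob_vectors: Sequence[np.ndarray], labels: Sequence[int]) -> float:
    """Mean categorical cross-entropy  -(1/N) sum log p_i[y_i].

    Natural logarithm; probabilities are clamped to [1e-12, 1] before the
    log, so a confidently wrong prediction yields a large finite loss.
    """
    if len(prob_vectors) != len(labels):
        raise ValueError("need one label per probability vector")
    if not prob_vectors:
        raise ValueError("CCE of an empty batch is undefined")
    total = 0.0
    for p, y in zip(prob_vectors, labels):
        p = np.asarray(p, dtype=float)
        if y < 0 or y >= p.shape[0]:
            raise ValueError(f"label {y} out of range for {p.shape[0]} classes")
        total += -np.log(min(max(p[y], EPS), 1.0))
    return total / len(prob_vectors)


def _pad_batch(examples: Sequence[TrainingExample], dim: int):
    B = len(examples)
    T = max((ex.vectors.shape[0] for ex in examples), default=0)
    T = max(T, 1)
    X = np.zeros((B, T, dim))
    mask = np.zeros((B, T))
    labels = np.zeros(B, dtype=int)
    for b, ex in enumerate(examples):
        L = ex.vectors.shape[0]
        if L:
            X[b, :L] = ex.vectors
            mask[b, :L] = 1.0
        labels[b] = ex.label
    return X, mask, labels


def _dataset_cce(model: SentimentGRU, examples: Sequence[TrainingExample]) -> float:
    X, mask, labels = _pad_batch(examples, model.config.input_dim)
    probs = _forward_batch(model, X, mask)
    return cce(list(probs), list(labels))


def train(
    config: RnnConfig,
    data: Sequence[TrainingExample],
    val: Sequence[TrainingExample] = (),
) -> tuple[SentimentGRU, LearningCurve]:
    """Train the classifier with Adam; reproducible for a fixed seed.

    Returns the trained model and per-epoch train/validation CCE
    (validation entries only when ``val`` is non-empty).
    """
    if not data:
        raise ValueError("training data must be non-empty")
    model = SentimentGRU(config)
    rng = np.random.default_rng(config.seed + 1)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    curve = LearningCurve()
    n = len(data)
    batch = max(1, min(config.batch_size, n))
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            chunk = [data[i] for i in order[start:start + batch]]
            X, mask, labels = _pad_batch(chunk, config.input_dim)
            targets = np.zeros((len(chunk), config.n_classes))
            targets[np.arange(len(chunk)), labels] = 1.0
            probs, cache = _forward_batch(model, X, mask, with_cache=True)
            grads = _backward_batch(model, X, mask, probs, targets, cache)
            step += 1
            for key, g in grads.items():
                m_state[key] = config.beta1 * m_state[key] + (1 - config.beta1) * g
                v_state[key] = config.beta2 * v_state[key] + (1 - config.beta2) * g * g
                m_hat = m_state[key] / (1 - config.beta1 ** step)
                v_hat = v_state[key] / (1 - config.beta2 ** step)
                model.params[key] -= (
                    config.learning_rate * m_hat / (np.sqrt(v_hat) + 1e-8)
                )
        curve.train.append(_dataset_cce(model, data))
        if val:
            curve.validation.append(_dataset_cce(model, val))
    return model, curve


def predict_document(
    model: SentimentGRU, table: EmbeddingTable, doc: RawDocument
) -> Prediction:
    """Classify a raw statement: clean, vectorize, forward, argmax.

    The emitted class is always -1 or +1; an empty document after cleaning
    cannot be classified.
    """
    seq = clean_and_tokenize(doc)
    if not seq.tokens:
        raise ValueError(f"document {doc.doc_id!r}: no tokens to classify")
    probs = forward(model, vectorize(seq, table))
    idx = int(np.argmax(probs))
    return Prediction(doc.doc_id, CLASS_OF_INDEX[idx], float(probs[idx]))


def predict_sequence(model: SentimentGRU, table: EmbeddingTable,
                     seq: TokenSequence) -> Prediction:
    """Classify an already-tokenized sequence (no cleaning)."""
    if not seq.tokens:
        raise ValueError(f"document {seq.doc_id!r}: no tokens to classify")
    probs = forward(model, vectorize(seq, table))
    idx = int(np.argmax(probs))
    return Prediction(seq.doc_id, CLASS_OF_INDEX[idx], float(probs[idx]))


def save_model(model: SentimentGRU, path: str | Path) -> None:
    """Single-file archive: named weight tensors plus a JSON config block."""
    from dataclasses import asdict

    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(asdict(model.config)).encode(), dtype=np.uint8
        ),
        **model.params,
    )


def load_model(path: str | Path) -> SentimentGRU:
    with np.load(path) as archive:
        config = RnnConfig(**json.loads(bytes(archive["__config__"]).decode()))
        params = {k: archive[k] for k in archive.files if k != "__config__"}
    return SentimentGRU(config, params)
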