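"""Recurrent classifier: forward oracle, loss, gradients, training."""

import math

import numpy as np
import pytest

from anotext.embeddings import EmbeddingTable
from anotext.gru import (
    RnnConfig,
    SentimentGRU,
    TrainingExample,
    _backward_batch,
    _forward_batch,
    _pad_batch,
    cce,
    forward,
    load_model,
    predict_document,
    save_model,
    train,
)
from anotext.textprep import RawDocument

# ---------------------------------------------------------------------------
# independent scalar unroll of the documented GRU recurrences (the oracle)


def _sig(x):
    return 1.0 / (1.0 + math.exp(-x))


def oracle_gru_unroll(params, prefix, xs):
    """Step-by-step GRU on one sequence, written independently with loops."""
    Wz, Wr, Wh = (params[f"{prefix}_{n}"] for n in ("Wz", "Wr", "Wh"))
    Uz, Ur, Uh = (params[f"{prefix}_{n}"] for n in ("Uz", "Ur", "Uh"))
    bz, br, bh = (params[f"{prefix}_{n}"] for n in ("bz", "br", "bh"))
    H = len(bz)
    h = [0.0] * H
    states = []
    for x in xs:
        z = [_sig(sum(x[i] * Wz[i][j] for i in range(len(x)))
                  + sum(h[i] * Uz[i][j] for i in range(H)) + bz[j])
             for j in range(H)]
        r = [_sig(sum(x[i] * Wr[i][j] for i in range(len(x)))
                  + sum(h[i] * Ur[i][j] for i in range(H)) + br[j])
             for j in range(H)]
        n = [math.tanh(sum(x[i] * Wh[i][j] for i in range(len(x)))
                       + sum(r[i] * h[i] * Uh[i][j] for i in range(H)) + bh[j])
             for j in range(H)]
        h = [(1.0 - z[j]) * h[j] + z[j] * n[j] for j in range(H)]
        states.append(list(h))
    return states


def oracle_forward(model, xs):
    """Full hand-unroll: BiGRU concat -> GRU -> dense -> softmax."""
    fwd = oracle_gru_unroll(model.params, "f", xs)
    bwd_rev = oracle_gru_unroll(model.params, "b", xs[::-1])
    bwd = bwd_rev[::-1]
    concat = [f + b for f, b in zip(fwd, bwd)]
    second = oracle_gru_unroll(model.params, "u", concat)
    final = second[-1] if second else [0.0] * model.config.uni_units
    W, b = model.params["out_W"], model.params["out_b"]
    logits = [sum(final[i] * W[i][k] for i in range(len(final))) + b[k]
              for k in range(model.config.n_classes)]
    mx = max(logits)
    ex = [math.exp(v - mx) for v in logits]
    s = sum(ex)
    return [v / s for v in ex]


@pytest.fixture
def tiny_model():
    return SentimentGRU(RnnConfig(input_dim=3, bi_units=2, uni_units=2, seed=11))


@pytest.mark.parametrize("length", [1, 2, 3])
def test_forward_matches_hand_unroll(tiny_model, length, rng):
    """Vectorized forward equals the independent step-by-step unroll."""
    xs = [list(rng.normal(size=3)) for _ in range(length)]
    got = forward(tiny_model, [np.array(x) for x in xs])
    want = oracle_forward(tiny_model, xs)
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_zero_output_layer_gives_uniform_probabilities(tiny_model, rng):
    tiny_model.params["out_W"][:] = 0.0
    tiny_model.params["out_b"][:] = 0.0
    probs = forward(tiny_model, [rng.normal(size=3) for _ in range(4)])
    np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)


def test_probabilities_normalized_for_random_weights(tiny_model, rng):
    for _ in range(5):
        probs = forward(tiny_model, [rng.normal(size=3)
                                     for _ in range(int(rng.integers(1, 6)))])
        assert probs.min() >= 0.0
        assert probs.sum() == pytest.approx(1.0)


def test_dimension_mismatch_rejected(tiny_model):
    with pytest.raises(ValueError, match="shape"):
        forward(tiny_model, [np.zeros(4)])


def test_bidirectional_reversal_symmetry(rng):
    """Reversing the input and swapping the two sub-units time-reverses the
    concatenated first-layer output with its halves exchanged."""
    from anotext.gru import _gru_layer_forward

    cfg = RnnConfig(input_dim=3, bi_units=2, uni_units=2, seed=5)
    model = SentimentGRU(cfg)
    X = rng.normal(size=(1, 4, 3))
    mask = np.ones((1, 4))

    def bigru_concat(params, X):
        Hf, _ = _gru_layer_forward(params, "f", X, mask)
        Hb_rev, _ = _gru_layer_forward(params, "b", X[:, ::-1], mask)
        return np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)

    Y = bigru_concat(model.params, X)
    swapped = {k.replace("f_", "t_").replace("b_", "f_").replace("t_", "b_"): v
               for k, v in model.params.items()}
    Y_rev = bigru_concat(swapped, X[:, ::-1])
    H = cfg.bi_units
    expected = np.concatenate([Y[:, ::-1, H:], Y[:, ::-1, :H]], axis=2)
    np.testing.assert_allclose(Y_rev, expected, atol=1e-12)


class TestCce:
    def test_perfect_prediction_is_zero(self):
        assert cce([np.array([0.0, 1.0])], [1]) == pytest.approx(0.0)

    def test_binary_uniform_is_ln2(self):
        assert cce([np.array([0.5, 0.5])], [0]) == pytest.approx(math.log(2))

    def test_batch_mean(self):
        probs = [np.array([1.0, 0.0]), np.array([0.5, 0.5])]
        assert cce(probs, [0, 1]) == pytest.approx(math.log(2) / 2)

    def test_zero_probability_clamped_finite(self):
        loss = cce([np.array([1.0, 0.0])], [1])
        assert np.isfinite(loss) and loss == pytest.approx(-math.log(1e-12))

    def test_validation(self):
        with pytest.raises(ValueError):
            cce([], [])
        with pytest.raises(ValueError):
            cce([np.array([1.0, 0.0])], [2])


def test_gradients_match_finite_differences(rng):
    """Analytic backpropagation equals central finite differences."""
    cfg = RnnConfig(input_dim=3, bi_units=2, uni_units=2, seed=7)
    model = SentimentGRU(cfg)
    exs = [TrainingExample(rng.normal(size=(T, 3)), int(rng.integers(2)))
           for T in (3, 1, 2)]
    X, mask, labels = _pad_batch(exs, 3)
    targets = np.zeros((3, 2))
    targets[np.arange(3), labels] = 1.0
    probs, cache = _forward_batch(model, X, mask, with_cache=True)
    grads = _backward_batch(model, X, mask, probs, targets, cache)

    def loss():
        return cce(list(_forward_batch(model, X, mask)), list(labels))

    eps = 1e-6
    for name, grad in grads.items():
        param = model.params[name]
        flat_indices = rng.choice(param.size, size=min(4, param.size),
                                  replace=False)
        for flat in flat_indices:
            idx = np.unravel_index(flat, param.shape)
            old = param[idx]
            param[idx] = old + eps
            up = loss()
            param[idx] = old - eps
            down = loss()
            param[idx] = old
            numeric = (up - down) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, abs=1e-6, rel=1e-4), name


class TestTraining:
    def make_separable(self, n, rng, dim=3):
        exs = []
        for i in range(n):
            y = i % 2
            base = np.ones(dim) if y else -np.ones(dim)
            T = int(rng.integers(2, 6))
            exs.append(TrainingExample(base + 0.1 * rng.normal(size=(T, dim)), y))
        return exs

    def test_overfits_separable_toy_set(self, rng):
        exs = self.make_separable(20, rng)
        cfg = RnnConfig(input_dim=3, bi_units=2, uni_units=2,
                        learning_rate=1e-2, epochs=200, batch_size=20, seed=3)
        model, curve = train(cfg, exs)
        acc = np.mean([int(np.argmax(forward(model, list(e.vectors)))) == e.label
                       for e in exs])
        assert acc == 1.0
        assert curve.train[-1] <= curve.train[0]

    def test_fixed_seed_reproducible(self, rng):
        exs = self.make_separable(10, rng)
        cfg = RnnConfig(input_dim=3, bi_units=2, uni_units=2,
                        learning_rate=1e-3, epochs=5, batch_size=4, seed=9)
        _, c1 = train(cfg, exs)
        _, c2 = train(cfg, exs)
        assert c1.train == c2.train

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train(RnnConfig(input_dim=3), [])

    def test_learning_curve_lengths(self, rng):
        exs = self.make_separable(8, rng)
        cfg = RnnConfig(input_dim=3, bi_units=2, uni_units=2, epochs=4,
                        batch_size=4, seed=0)
        _, curve = train(cfg, exs, val=exs[:2])
        assert len(curve.train) == len(curve.validation) == 4


def test_predict_document_contract(rng):
    cfg = RnnConfig(input_dim=4, bi_units=2, uni_units=2, seed=1)
    model = SentimentGRU(cfg)
    table = EmbeddingTable(4, {"fat": rng.normal(size=4),
                               "salad": rng.normal(size=4)})
    pred = predict_document(model, table, RawDocument("d", "Fat, salad!"))
    assert pred.klass in (-1, 1)
    assert 0.5 <= pred.probability <= 1.0
    with pytest.raises(ValueError, match="no tokens"):
        predict_document(model, table, RawDocument("d", "!!!"))


def test_model_roundtrip(tmp_path, rng):
    cfg = RnnConfig(input_dim=3, bi_units=2, uni_units=2, seed=2)
    model = SentimentGRU(cfg)
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert back.config == cfg
    xs = [rng.normal(size=3) for _ in range(3)]
    np.testing.assert_array_equal(forward(model, xs), forward(back, xs))


def test_config_validation():
    with pytest.raises(ValueError):
        RnnConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        RnnConfig(beta1=1.0)
    with pytest.raises(ValueError):
        RnnConfig(bi_units=0)
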