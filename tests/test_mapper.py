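"""The masked LSTM mapper: gradients, masking, determinism, learning."""

import numpy as np
import pytest

from iconotrans import (
    EncodedWord,
    MapperConfig,
    encode_word,
    make_feature_table,
    predict,
    train_classifier,
    train_regressor,
)
from iconotrans import mapper as M


def _random_words(table, n, rng, min_len=2, max_len=10):
    words = []
    for _ in range(n):
        length = rng.integers(min_len, max_len + 1)
        phones = [table.symbols[i] for i in rng.integers(0, len(table), size=length)]
        words.append(encode_word(phones, table))
    return words


@pytest.fixture(scope="module")
def table():
    return make_feature_table(10, 6, seed=1)


class TestGradients:
    """Analytic BPTT checked against central finite differences."""

    @pytest.mark.parametrize(
        "activation,loss",
        [("linear", "cos"), ("relu", "cos"), ("softmax", "ce")],
    )
    def test_backward_matches_finite_differences(self, activation, loss):
        rng = np.random.default_rng(0)
        B, T, F, H, O = 4, 8, 3, 5, 3
        X = rng.standard_normal((B, T, F))
        mask = np.zeros((B, T))
        for i, length in enumerate(rng.integers(2, T + 1, size=B)):
            mask[i, :length] = 1.0
        X *= mask[:, :, None]
        cfg = MapperConfig(
            hidden_units=H,
            output_dim=O,
            dropout=0.0,
            recurrent_dropout=0.0,
            output_activation=activation,
            loss="negative_cosine" if loss == "cos" else "categorical_cross_entropy",
        )
        params = M._init_params(cfg, F, np.random.default_rng(1))
        if loss == "cos":
            Y = rng.standard_normal((B, O))
        else:
            Y = np.eye(O)[rng.integers(0, O, size=B)]

        def loss_value():
            h = M._forward(params, X, mask)
            out, _ = M._head(params, h, activation)
            if loss == "cos":
                return M._cosine_loss_and_grad(out, Y)[0]
            return M._ce_loss_and_grad(out, Y)[0]

        h, steps = M._forward(params, X, mask, cache=True)
        out, z = M._head(params, h, activation)
        if loss == "cos":
            _, dy, _ = M._cosine_loss_and_grad(out, Y)
            dz = dy * (z > 0) if activation == "relu" else dy
        else:
            _, dz = M._ce_loss_and_grad(out, Y)
        grads = {"Wy": h.T @ dz, "by": dz.sum(axis=0)}
        grads.update(M._backward(params, steps, dz @ params["Wy"].T))

        eps = 1e-6
        for key in params:
            numeric = np.zeros_like(params[key])
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = params[key][ix]
                params[key][ix] = orig + eps
                lp = loss_value()
                params[key][ix] = orig - eps
                lm = loss_value()
                params[key][ix] = orig
                numeric[ix] = (lp - lm) / (2 * eps)
            scale = max(np.abs(numeric).max(), 1e-8)
            assert np.abs(numeric - grads[key]).max() / scale < 1e-5, key


class TestRegressor:
    def test_learns_degenerate_constant_target(self, table):
        rng = np.random.default_rng(2)
        target = np.zeros(8)
        target[0] = 1.0
        pairs = [(w, target) for w in _random_words(table, 60, rng)]
        cfg = MapperConfig(
            hidden_units=12,
            output_dim=8,
            output_activation="linear",
            epochs=30,
            dropout=0.0,
            recurrent_dropout=0.0,
            seed=0,
        )
        model = train_regressor(pairs, cfg)
        preds = predict(model, [w for w, _ in pairs])
        cosines = [
            p @ target / (np.linalg.norm(p) * np.linalg.norm(target)) for p in preds
        ]
        assert np.mean(cosines) > 0.99

    def test_reported_final_metric_matches_external_recompute(self, table):
        rng = np.random.default_rng(3)
        pairs = [
            (w, rng.standard_normal(4)) for w in _random_words(table, 40, rng)
        ]
        cfg = MapperConfig(
            hidden_units=8, output_dim=4, output_activation="linear", epochs=2, seed=1
        )
        model = train_regressor(pairs, cfg)
        preds = predict(model, [w for w, _ in pairs])
        external = np.mean(
            [
                p @ t / (np.linalg.norm(p) * np.linalg.norm(t))
                for p, (_, t) in zip(preds, pairs)
            ]
        )
        assert abs(model.final_train_metric - external) < 1e-5

    def test_dimension_mismatch_and_empty_rejected(self, table):
        rng = np.random.default_rng(4)
        pairs = [(w, np.ones(3)) for w in _random_words(table, 4, rng)]
        with pytest.raises(ValueError):
            train_regressor(pairs, MapperConfig(hidden_units=4, output_dim=5))
        with pytest.raises(ValueError):
            train_regressor([], MapperConfig(hidden_units=4, output_dim=3))


class TestClassifier:
    def test_learns_separable_classes_keyed_to_first_phone(self, table):
        # class = sign of the first phone's first feature: linearly separable
        rng = np.random.default_rng(5)
        pos = [s for s, row in zip(table.symbols, table.matrix) if row[0] > 0]
        neg = [s for s, row in zip(table.symbols, table.matrix) if row[0] < 0]
        assert pos and neg
        pairs = []
        for _ in range(80):
            label = rng.integers(0, 2)
            first = rng.choice(pos if label else neg)
            rest = [table.symbols[i] for i in rng.integers(0, len(table), size=3)]
            onehot = np.eye(2)[label]
            pairs.append((encode_word([first] + rest, table), onehot))
        cfg = MapperConfig(
            hidden_units=12,
            output_dim=2,
            output_activation="softmax",
            loss="categorical_cross_entropy",
            epochs=25,
            dropout=0.0,
            recurrent_dropout=0.0,
            seed=2,
        )
        model = train_classifier(pairs, cfg)
        preds = predict(model, [w for w, _ in pairs])
        acc = np.mean(
            [p.argmax() == t.argmax() for p, (_, t) in zip(preds, pairs)]
        )
        assert acc > 0.95

    def test_softmax_outputs_on_simplex(self, table):
        rng = np.random.default_rng(6)
        pairs = [
            (w, np.eye(3)[rng.integers(0, 3)]) for w in _random_words(table, 30, rng)
        ]
        cfg = MapperConfig(
            hidden_units=6,
            output_dim=3,
            output_activation="softmax",
            loss="categorical_cross_entropy",
            epochs=1,
            seed=3,
        )
        model = train_classifier(pairs, cfg)
        preds = predict(model, _random_words(table, 100, rng))
        for p in preds:
            assert abs(p.sum() - 1.0) < 1e-6
            assert (p >= 0).all()

    def test_loss_activation_coupling_enforced(self):
        with pytest.raises(ValueError):
            MapperConfig(loss="categorical_cross_entropy", output_activation="relu").validate()
        with pytest.raises(ValueError):
            MapperConfig(loss="negative_cosine", output_activation="softmax").validate()


@pytest.fixture(scope="module")
def model(table):
    rng = np.random.default_rng(7)
    pairs = [(w, rng.standard_normal(5)) for w in _random_words(table, 30, rng)]
    cfg = MapperConfig(
        hidden_units=8, output_dim=5, output_activation="relu", epochs=1, seed=4
    )
    return train_regressor(pairs, cfg)


class TestPredictionContracts:

    def test_same_seed_gives_bitwise_identical_predictions(self, table):
        rng = np.random.default_rng(8)
        words = _random_words(table, 20, rng)
        targets = [np.abs(np.random.default_rng(9).standard_normal(4)) for _ in words]
        pairs = list(zip(words, targets))
        cfg = MapperConfig(hidden_units=6, output_dim=4, epochs=2, seed=11)
        p1 = predict(train_regressor(pairs, cfg), words)
        p2 = predict(train_regressor(pairs, cfg), words)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a, b)

    def test_prediction_depends_only_on_unmasked_prefix(self, model, table):
        word = encode_word(table.symbols[:3], table)
        corrupted = EncodedWord(
            matrix=word.matrix.copy(), mask=word.mask.copy(), length=word.length
        )
        corrupted.matrix[word.length :] = 99.0  # garbage beyond the mask
        p_clean = predict(model, [word])[0]
        p_corrupt = predict(model, [corrupted])[0]
        np.testing.assert_array_equal(p_clean, p_corrupt)

    def test_batching_does_not_change_results(self, model, table):
        rng = np.random.default_rng(10)
        words = _random_words(table, 7, rng)
        single = [predict(model, [w])[0] for w in words]
        batched = predict(model, words, batch_size=7)
        for a, b in zip(single, batched):
            np.testing.assert_allclose(a, b, atol=1e-5)

    def test_relu_outputs_nonnegative(self, model, table):
        rng = np.random.default_rng(11)
        for p in predict(model, _random_words(table, 10, rng)):
            assert (p >= 0).all()

    def test_empty_input_gives_empty_output(self, model):
        assert predict(model, []) == []

    def test_shape_mismatch_rejected(self, model):
        bad = EncodedWord(
            matrix=np.zeros((15, 99)), mask=np.zeros(15, dtype=bool), length=1
        )
        with pytest.raises(ValueError):
            predict(model, [bad])
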