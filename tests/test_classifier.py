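"""The bi-LSTM phrase classifier: build, train, score, evaluate."""

import numpy as np
import pytest

from metaner.classifier import BiLSTMClassifier, evaluate_classifier
from metaner.corpus import PAD_ID
from metaner.embedding import EmbeddingModel


@pytest.fixture()
def tiny_model(rng):
    vecs = rng.standard_normal((12, 6))
    return EmbeddingModel({f"w{i}": i for i in range(12)}, vecs)


def _clf(tiny_model, **kw):
    params = dict(embedding=tiny_model, hidden_units=5, max_len=7,
                  n_categories=3, random_state=0, dropout=0.0)
    params.update(kw)
    return BiLSTMClassifier(**params)


def _random_X(rng, n, max_len=7, vocab=12):
    X = rng.integers(1, vocab + 1, size=(n, max_len))
    # right-pad a random suffix
    for row in X:
        k = rng.integers(2, max_len + 1)
        row[k:] = PAD_ID
    return X


class TestBuild:
    def test_output_layer_width_matches_categories(self, tiny_model, rng):
        clf = _clf(tiny_model, n_categories=11)
        clf.fit(_random_X(rng, 30), rng.integers(0, 11, size=30))
        assert clf.predict_proba(_random_X(rng, 4)).shape == (4, 11)

    def test_untrained_scores_in_unit_interval(self, tiny_model, rng):
        clf = _clf(tiny_model)
        clf.fit(_random_X(rng, 10), rng.integers(0, 3, size=10))
        p = clf.predict_proba(_random_X(rng, 20))
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_same_seed_same_initial_parameters(self, tiny_model):
        a = _clf(tiny_model)
        b = _clf(tiny_model)
        rng_a = np.random.default_rng(0)
        rng_b = np.random.default_rng(0)
        a._build(rng_a, 3)
        b._build(rng_b, 3)
        np.testing.assert_array_equal(a._fwd.Wx, b._fwd.Wx)
        np.testing.assert_array_equal(a._bwd.Wh, b._bwd.Wh)

    def test_fewer_than_two_categories_fatal(self, tiny_model, rng):
        clf = _clf(tiny_model, n_categories=1)
        with pytest.raises(ValueError):
            clf.fit(_random_X(rng, 5), np.zeros(5, dtype=int))


class TestTraining:
    def test_step_count(self, tiny_model, rng):
        X = _random_X(rng, 1000)
        y = rng.integers(0, 3, size=1000)
        clf = _clf(tiny_model, batch_size=100, epochs=1).fit(X, y)
        assert len(clf.training_log_) == 10  # 1000 / 100 steps, one epoch

    def test_loss_decreases_on_separable_fixture(self, tiny_model, rng):
        # tokens 1-4 -> class 0, 5-8 -> class 1 (linearly separable)
        n = 400
        y = rng.integers(0, 2, size=n)
        X = np.full((n, 7), PAD_ID, dtype=np.int64)
        for i in range(n):
            lo = 1 if y[i] == 0 else 5
            X[i, :3] = rng.integers(lo, lo + 4, size=3)
        clf = _clf(tiny_model, n_categories=2, epochs=3, batch_size=50,
                   learning_rate=0.01).fit(X, y)
        assert np.mean(clf.training_log_[-3:]) < clf.training_log_[0]
        assert (clf.predict(X) == y).mean() > 0.9

    def test_same_seed_identical_metrics(self, tiny_model, rng):
        X = _random_X(rng, 200)
        y = rng.integers(0, 3, size=200)
        m = []
        for _ in range(2):
            clf = _clf(tiny_model, dropout=0.5).fit(X, y)
            m.append(clf.predict_proba(X))
        np.testing.assert_array_equal(m[0], m[1])

    def test_mislabeled_inputs_fatal(self, tiny_model, rng):
        clf = _clf(tiny_model, n_categories=3)
        with pytest.raises(ValueError):
            clf.fit(_random_X(rng, 10), np.full(10, 5))


class TestScoring:
    def test_inference_deterministic_bitwise(self, tiny_model, rng):
        clf = _clf(tiny_model, dropout=0.5)
        clf.fit(_random_X(rng, 50), rng.integers(0, 3, size=50))
        X = _random_X(rng, 10)
        a = clf.predict_proba(X)
        b = clf.predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_all_padding_input_is_the_baseline(self, tiny_model, rng):
        clf = _clf(tiny_model)
        clf.fit(_random_X(rng, 30), rng.integers(0, 3, size=30))
        pad = np.full(7, PAD_ID, dtype=np.int64)
        np.testing.assert_array_equal(clf.baseline_scores_,
                                      clf.score_tokens(pad))

    def test_trained_fixture_recovers_planted_category(
            self, trained_clf, corpus_split):
        X, y = corpus_split.arrays("test")
        assert (trained_clf.predict(X) == y).mean() >= 0.95


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, tiny_model, rng):
        """Analytic BPTT gradients agree with central differences."""
        clf = _clf(tiny_model, hidden_units=4, n_categories=3)
        clf._build(np.random.default_rng(1), 3)
        X = _random_X(rng, 5, max_len=7)
        y = rng.integers(0, 3, size=5)

        def loss_at():
            caches = {}
            p = clf._forward(X, caches=caches)
            loss, _ = clf._loss_and_dz(p, y)
            return loss, caches

        loss, caches = loss_at()
        _, dz = clf._loss_and_dz(caches["p"], y)
        grads, _ = clf._backward(caches, dz)
        params = (clf._fwd.params() + clf._bwd.params() + [clf._Wd, clf._bd])
        eps = 1e-6
        for p_arr, g_arr in zip(params, grads):
            flat = p_arr.ravel()
            idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = loss_at()
                flat[i] = orig - eps
                lm, _ = loss_at()
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g_arr.ravel()[i] == pytest.approx(numeric, rel=1e-4,
                                                         abs=1e-7)


class TestEvaluation:
    def test_perfect_scores_degenerate_case(self):
        y = np.array([0, 1, 2, 0])
        p = np.zeros((4, 3))
        p[np.arange(4), y] = 1.0

        class _Fake:
            n_categories_ = 3

            def predict_proba(self, X):
                return p

        m = evaluate_classifier(_Fake(), np.zeros((4, 7)), y)
        assert m.accuracy == 1.0
        assert all(v == 1.0 for v in m.per_category_auroc.values())
        assert m.micro_average_auroc == 1.0

    def test_label_independent_scores_give_half_auroc(self, rng):
        n = 4000
        y = rng.integers(0, 2, size=n)
        p = rng.random((n, 2))

        class _Fake:
            n_categories_ = 2

            def predict_proba(self, X):
                return p

        m = evaluate_classifier(_Fake(), np.zeros((n, 7)), y)
        assert m.micro_average_auroc == pytest.approx(0.5, abs=0.03)

    def test_twenty_example_hand_tally(self, rng):
        # brute-force confusion arithmetic on a fixed toy set
        y = np.array([0] * 8 + [1] * 7 + [2] * 5)
        p = rng.random((20, 3))

        class _Fake:
            n_categories_ = 3

            def predict_proba(self, X):
                return p

        m = evaluate_classifier(_Fake(), np.zeros((20, 7)), y)
        yhat = p.argmax(axis=1)
        acc = sum(int(a == b) for a, b in zip(y, yhat)) / 20
        assert m.accuracy == pytest.approx(acc)
        conf = np.zeros((3, 3))
        for t, pr in zip(y, yhat):
            conf[t, pr] += 1
        np.testing.assert_allclose(
            m.confusion, conf / conf.sum(axis=1, keepdims=True))
        # micro precision == recall == accuracy for single-label problems
        assert m.precision_micro == pytest.approx(acc)
        assert m.recall_micro == pytest.approx(acc)

    def test_confusion_rows_sum_to_one(self, trained_clf, corpus_split):
        X, y = corpus_split.arrays("test")
        m = evaluate_classifier(trained_clf, X, y, corpus_split.categories)
        present = np.unique(y)
        np.testing.assert_allclose(m.confusion[present].sum(axis=1), 1.0)

    def test_absent_category_auroc_undefined(self, rng):
        y = np.array([0, 0, 1, 1])  # category 2 absent
        p = rng.random((4, 3))

        class _Fake:
            n_categories_ = 3

            def predict_proba(self, X):
                return p

        m = evaluate_classifier(_Fake(), np.zeros((4, 7)), y)
        assert np.isnan(m.per_category_auroc["2"])
        assert not np.isnan(m.micro_average_auroc)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, tiny_model, rng):
        clf = _clf(tiny_model).fit(_random_X(rng, 40),
                                   rng.integers(0, 3, size=40))
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = BiLSTMClassifier.load(path)
        X = _random_X(rng, 8)
        np.testing.assert_array_equal(clf.predict_proba(X),
                                      loaded.predict_proba(X))
        np.testing.assert_array_equal(clf.baseline_scores_,
                                      loaded.baseline_scores_)
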