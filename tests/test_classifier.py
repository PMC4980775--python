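"""Window instance construction, forward/backward pass, AdaDelta and the
training loop."""

import numpy as np
import pytest

from conftest import check_classifier_gradients
from deptrig.classifier import (
    AdaDeltaState,
    ModelParams,
    TrainConfig,
    TriggerInstance,
    _forward_pass,
    adadelta_update,
    build_instances,
    fit,
    forward,
    init_params,
    load_model,
    lookup_concat,
    loss_and_gradients,
    predict,
    save_model,
)
from deptrig.sgns import EmbeddingMatrix, Vocabulary


def make_embedding(words, size=4, seed=0):
    vocab = Vocabulary(items=list(words), counts=list(range(len(words), 0, -1)))
    rng = np.random.default_rng(seed)
    return EmbeddingMatrix(vocab, rng.normal(size=(len(words), size)))


class TestBuildInstances:
    def test_stopword_removed_before_windowing(self):
        emb_index = {"thalidomide": 0, "inhibited": 1, "formation": 2}
        sents = [
            (
                "d",
                0,
                ["Thalidomide", "inhibited", "the", "formation"],
                ["NONE", "Regulation", "NONE", "NONE"],
            )
        ]
        inst = build_instances(sents, emb_index, k=1, stopwords=frozenset({"the"}))
        center = [i for i in inst if i.gold == "Regulation"][0]
        # the window skips "the": Thalidomide and formation flank the trigger
        assert center.window_ids == (0, 1, 2)
        assert center.token_index == 1

    def test_padding_at_sentence_edges(self):
        inst = build_instances(
            [("d", 0, ["grows"], ["NONE"])], {"grows": 0}, k=2, stopwords=frozenset()
        )
        pad = 1  # |vocab|
        assert inst[0].window_ids == (pad, pad, 0, pad, pad)

    def test_all_stopwords_no_instances(self):
        inst = build_instances(
            [("d", 0, ["the", "of"], ["NONE", "NONE"])], {}, k=1, stopwords=frozenset({"the", "of"})
        )
        assert inst == []

    def test_unknown_words_map_to_unk(self):
        inst = build_instances(
            [("d", 0, ["mystery"], ["NONE"])], {"known": 0}, k=0, stopwords=frozenset()
        )
        assert inst[0].window_ids == (2,)  # |vocab| + 1


class TestLookupConcat:
    W = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [0.0, 0.0]])

    def test_k_zero_is_identity(self):
        assert np.array_equal(lookup_concat([1], self.W), [3.0, 4.0])

    def test_concatenation_order(self):
        assert np.array_equal(lookup_concat([0, 1, 2], self.W), [1, 2, 3, 4, 5, 6])

    def test_all_pad_window_is_zero_vector(self):
        assert np.array_equal(lookup_concat([3, 3, 3], self.W), np.zeros(6))

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            lookup_concat([4], self.W)


def small_params(n_classes=3, zero=False, seed=0, layers=1, k=1, size=3):
    emb = make_embedding([f"w{i}" for i in range(5)], size=size, seed=seed)
    cfg = TrainConfig(k=k, layers=layers, hidden_size=4, dropout=0.5, seed=seed)
    classes = ["NONE"] + [f"C{i}" for i in range(n_classes - 1)]
    params = init_params(emb, classes, cfg, np.random.default_rng(seed))
    if zero:
        params.hidden = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params.hidden]
        params.out = (np.zeros_like(params.out[0]), np.zeros_like(params.out[1]))
    return params


class TestForward:
    def test_probabilities_sum_to_one(self):
        params = small_params()
        x = np.random.default_rng(1).normal(size=(2 * 1 + 1) * 3)
        probs = forward(params, x)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_network_is_uniform(self):
        params = small_params(n_classes=4, zero=True)
        probs = forward(params, np.ones(9))
        assert np.allclose(probs, 0.25)

    def test_inference_is_deterministic(self):
        params = small_params()
        x = np.ones(9)
        assert np.array_equal(forward(params, x), forward(params, x))

    def test_train_mode_requires_rng(self):
        params = small_params()
        with pytest.raises(ValueError):
            forward(params, np.ones(9), mode="train", dropout=0.5)

    def test_dropout_mean_approaches_infer_activation(self):
        params = small_params(seed=3)
        X = np.abs(np.random.default_rng(2).normal(size=(1, 9))) + 0.5
        _, acts_infer, _, _ = _forward_pass(params, X, "infer", None, 0.0)
        target = acts_infer[-1][0]
        rng = np.random.default_rng(7)
        total = np.zeros_like(target)
        n = 10_000
        for _ in range(n):
            _, acts, _, _ = _forward_pass(params, X, "train", rng, 0.5)
            total += acts[-1][0]
        mean = total / n
        active = target > 1e-6
        assert active.any()
        assert np.all(np.abs(mean[active] - target[active]) / target[active] < 0.05)


class TestLossAndGradients:
    def test_confident_correct_prediction_has_near_zero_loss(self):
        params = small_params(n_classes=2, zero=True)
        # push the output layer to always pick class 1
        params.out = (params.out[0], np.array([-20.0, 20.0]))
        ids = np.array([[0, 1, 2]])
        loss, *_ = loss_and_gradients(params, ids, np.array([1]), dropout=0.0)
        assert loss < 1e-8

    def test_static_mode_gives_no_embedding_gradient(self):
        params = small_params()
        params.trainable_embedding = False
        _, gW, _, _ = loss_and_gradients(params, np.array([[0, 1, 2]]), np.array([0]), dropout=0.0)
        assert gW is None

    def test_pad_row_gradient_is_zero(self):
        params = small_params()
        ids = np.array([[params.pad_index, 0, params.pad_index]])
        _, gW, _, _ = loss_and_gradients(params, ids, np.array([0]), dropout=0.0)
        assert np.all(gW[params.pad_index] == 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_gradients_match_central_differences(self, seed):
        check_classifier_gradients(np.random.default_rng(seed), tol=1e-5)


class TestAdaDelta:
    def test_zero_gradient_no_update(self):
        g = np.zeros(3)
        delta, eg2, edx2 = adadelta_update(g, np.zeros(3), np.zeros(3))
        assert np.all(delta == 0.0)

    def test_first_step_magnitude_closed_form(self):
        delta, _, _ = adadelta_update(np.array([1.0]), np.zeros(1), np.zeros(1), rho=0.95, eps=1e-6)
        expected = -np.sqrt(1e-6) / np.sqrt(0.05 + 1e-6)
        assert delta[0] == pytest.approx(expected, abs=1e-12)

    def test_identical_gradient_histories_identical_updates(self):
        state = AdaDeltaState([np.zeros(2)], rho=0.9, eps=1e-6)
        arr = np.zeros(2)
        for g in ([1.0, 1.0], [-0.5, -0.5], [2.0, 2.0]):
            state.step([arr], [np.array(g)])
        assert arr[0] == arr[1]


def separable_instances(n_per_class=40, k=1):
    """Two classes fully determined by the center word id."""
    inst = []
    for i in range(n_per_class):
        inst.append(TriggerInstance("d", 0, i, (0, 1, 2), "NONE"))
        inst.append(TriggerInstance("d", 1, i, (3, 4, 2), "Regulation"))
    return inst


class TestFit:
    def _emb(self):
        return make_embedding(["a", "b", "c", "x", "y"], size=6, seed=4)

    def _cfg(self, **kw):
        base = dict(k=1, layers=1, hidden_size=8, dropout=0.0, batch=16, max_epochs=50, patience=50, seed=2)
        base.update(kw)
        return TrainConfig(**base)

    def test_separable_problem_reaches_low_loss(self):
        inst = separable_instances()
        result = fit(inst, [], self._emb(), self._cfg())
        assert result.log[-1]["train_loss"] < 0.3
        assert result.log[-1]["train_loss"] < result.log[0]["train_loss"] / 3

    def test_same_seed_reproduces_parameters(self):
        inst = separable_instances()
        a = fit(inst, [], self._emb(), self._cfg())
        b = fit(inst, [], self._emb(), self._cfg())
        assert np.array_equal(a.params.W, b.params.W)
        assert all(
            np.array_equal(w1, w2) and np.array_equal(b1, b2)
            for (w1, b1), (w2, b2) in zip(a.params.hidden, b.params.hidden)
        )

    def test_zero_patience_runs_exactly_one_epoch(self):
        result = fit(separable_instances(), [], self._emb(), self._cfg(patience=0))
        assert len(result.log) == 1

    def test_static_mode_leaves_embedding_rows_untouched(self):
        emb = self._emb()
        result = fit(
            separable_instances(), [], emb, self._cfg(static=True, max_epochs=3, patience=3)
        )
        assert np.array_equal(result.params.W[: len(emb.vocab)], emb.vectors)

    def test_fitted_model_reproduces_training_labels(self):
        emb = self._emb()
        result = fit(separable_instances(), [], emb, self._cfg())
        sents = [("d", 0, ["a", "b", "c"]), ("d", 1, ["x", "y", "c"])]
        pred = predict(result.params, sents, stopwords=frozenset())
        assert pred[1][0] == "Regulation" or pred[1][1] == "Regulation"
        flat_true = ["NONE"] * 3 + ["Regulation"] * 3
        flat_pred = pred[0] + pred[1]
        agree = sum(t == p for t, p in zip(flat_true, flat_pred))
        assert agree / 6 >= 0.5  # coarse: the toy maps word ids, not positions

    def test_requires_instances_and_classes(self):
        with pytest.raises(ValueError):
            fit([], [], self._emb(), self._cfg())


class TestPredict:
    def test_zero_model_predicts_first_class(self):
        params = small_params(zero=True)
        pred = predict(params, [("d", 0, ["w0", "w1"])], stopwords=frozenset())
        assert pred == [["NONE", "NONE"]]  # NONE is class 0 by declared order

    def test_stopwords_forced_to_none(self):
        params = small_params()
        # bias the output so the model never answers NONE on real tokens
        params.out = (params.out[0] * 0, np.array([-10.0, 10.0, -10.0]))
        pred = predict(params, [("d", 0, ["the", "w0"])])
        assert pred[0][0] == "NONE"
        assert pred[0][1] == "C0"


def test_model_archive_round_trip(tmp_path):
    params = small_params(seed=9)
    path = tmp_path / "model.npz"
    save_model(params, str(path))
    again = load_model(str(path))
    assert np.array_equal(again.W, params.W)
    assert again.classes == params.classes
    assert again.vocab_index == params.vocab_index
    assert again.k == params.k
    x = np.ones((2 * params.k + 1) * params.size)
    assert np.allclose(forward(again, x), forward(params, x))
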