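"""Splitting, the classical classifier suite, and the LSTM correctness
oracles (hand evaluation, finite-difference gradients, convergence)."""

import math

import numpy as np
import pandas as pd
import pytest

import wearsleep as ws
from wearsleep.lstm import (
    TrainConfig,
    init_params,
    lstm_backward,
    lstm_forward,
    lstm_loss,
    train_lstm,
    zero_params,
    LSTMParams,
)
from wearsleep.models import DEFAULT_GRIDS, SplitSpec, evaluate_at_ns, fit_memoryless, memory_sweep, predict_sequence
from wearsleep.windowing import make_windows


def toy_windows(n=100, seed=0, n_classes=4, groups=None):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), n // n_classes).astype(str)
    X = rng.normal(0, 0.2, size=(n, 1, 2)) + y.astype(float)[:, None, None]
    return ws.WindowedDataset(ns=0, X=X, y=y, feature_names=["f0", "f1"], groups=groups)


class TestSplit:
    def test_stratified_preserves_class_counts(self):
        ds = toy_windows(100)
        train, test = ws.split(ds, SplitSpec(seed=0))
        assert len(train) == 75 and len(test) == 25
        for c in "0123":
            assert abs((train.y == c).sum() - 18.75) <= 1

    def test_subject_held_out_keeps_subjects_whole(self):
        groups = np.repeat(["s1", "s2"], 50)
        ds = toy_windows(100, groups=groups)
        train, test = ws.split(ds, SplitSpec(strategy="subject_held_out", seed=1))
        assert set(train.groups).isdisjoint(set(test.groups))

    def test_same_seed_identical_partition(self):
        ds = toy_windows(100)
        t1, _ = ws.split(ds, SplitSpec(seed=3))
        t2, _ = ws.split(ds, SplitSpec(seed=3))
        assert t1.X == pytest.approx(t2.X)

    def test_missing_class_in_train_raises(self):
        ds = toy_windows(8, n_classes=4)
        ds.y[:] = np.array(["0"] * 7 + ["1"])
        with pytest.raises(ValueError):
            ws.split(ds, SplitSpec(train_fraction=0.5, seed=0))


class TestMemoryless:
    @pytest.mark.parametrize("name", ["LR", "RF", "kNN", "SVM", "MLP"])
    def test_separable_toy_reaches_perfect_train_accuracy(self, name):
        rng = np.random.default_rng(1)
        y = np.repeat(["a", "b"], 40)
        X = rng.normal(0, 0.2, (80, 2)) + (y == "b")[:, None] * 4.0
        clf = fit_memoryless(X, y, name, grid={})
        assert (clf.predict(X) == y).mean() == 1.0

    def test_grid_of_size_one_returns_that_point(self):
        rng = np.random.default_rng(2)
        y = np.repeat(["a", "b"], 30)
        X = rng.normal(0, 1, (60, 2)) + (y == "b")[:, None] * 2
        clf = fit_memoryless(X, y, "kNN", grid={"n_neighbors": [3]})
        assert clf.chosen_params_ == {"n_neighbors": 3}
        assert clf.get_params()["n_neighbors"] == 3

    def test_grid_search_records_choice(self):
        rng = np.random.default_rng(3)
        y = np.repeat(["a", "b"], 40)
        X = rng.normal(0, 1, (80, 2)) + (y == "b")[:, None] * 2
        clf = fit_memoryless(X, y, "kNN", grid={"n_neighbors": [3, 5]})
        assert clf.chosen_params_["n_neighbors"] in (3, 5)

    def test_default_grids_within_stated_model_budget(self):
        for name, grid in DEFAULT_GRIDS.items():
            n_points = int(np.prod([len(v) for v in grid.values()]))
            assert 1 <= n_points * 3 <= 1000  # grid × cv folds

    def test_single_class_train_rejected(self):
        with pytest.raises(ValueError):
            fit_memoryless(np.zeros((10, 2)), np.zeros(10), "RF")

    def test_shuffled_labels_cannot_beat_chance(self, feature_pool):
        # leakage guard: windowing+split must not let a model beat the
        # majority rate when labels carry no signal (memorizing noise may
        # legitimately score below it)
        rng = np.random.default_rng(0)
        table = feature_pool.copy()
        shuffled = rng.permutation(table.frame["stage"].to_numpy())
        table.frame["stage"] = shuffled
        rep = evaluate_at_ns(table, 0, TrainConfig(seed=0), model="RF")
        majority = pd.Series(shuffled).value_counts(normalize=True).max()
        assert rep.accuracy <= majority + 0.05


class TestLSTMForward:
    def test_zero_weights_give_zero_states_uniform_probs(self):
        p = zero_params(3, 4, np.array(["w", "x", "y", "z"]))
        h, c, probs = lstm_forward(np.random.default_rng(0).normal(size=(5, 3)), p)
        assert (h == 0).all() and (c == 0).all()
        assert probs == pytest.approx(0.25)

    def test_hand_evaluated_two_step_scalar_cell(self):
        # one hidden unit, one feature; every gate written out by hand
        wf, uf, bf = 0.5, 0.25, 0.1
        wi, ui, bi = 0.3, 0.2, 0.0
        wo, uo, bo = 0.4, 0.1, -0.1
        wc, uc, bc = 0.6, 0.3, 0.2
        p = LSTMParams(
            wx=np.array([[wf, wi, wo, wc]]),
            wh=np.array([[uf, ui, uo, uc]]),
            b=np.array([bf, bi, bo, bc]),
            v=np.array([[1.0, -1.0]]),
            b_y=np.zeros(2),
            classes=np.array(["a", "b"]),
        )
        x = [1.0, -0.5]
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        h_prev, c_prev = 0.0, 0.0
        for xt in x:
            f = sig(wf * xt + uf * h_prev + bf)
            i = sig(wi * xt + ui * h_prev + bi)
            o = sig(wo * xt + uo * h_prev + bo)
            g = math.tanh(wc * xt + uc * h_prev + bc)
            c_prev = i * g + f * c_prev
            h_prev = o * math.tanh(c_prev)
        h_seq, c_seq, probs = lstm_forward(np.array(x).reshape(2, 1), p)
        assert h_seq[-1, 0] == pytest.approx(h_prev, abs=1e-12)
        assert c_seq[-1, 0] == pytest.approx(c_prev, abs=1e-12)
        logit = h_prev * 1.0, h_prev * -1.0
        z = math.exp(logit[0]) + math.exp(logit[1])
        assert probs[0] == pytest.approx(math.exp(logit[0]) / z, abs=1e-12)

    def test_gate_and_hidden_ranges(self, rng):
        p = init_params(3, 5, np.arange(4), seed=2, scale=1.0)
        X = rng.normal(size=(8, 6, 3))
        h, c, _, cache = lstm_forward(X, p, return_cache=True)
        for gate in ("f", "i", "o"):
            for step in cache[gate]:
                assert ((step > 0) & (step < 1)).all()
        assert (np.abs(h) < 1).all()

    def test_sigmoid_candidate_variant(self):
        p = zero_params(2, 3, np.arange(2))
        p.candidate_activation = "sigmoid"
        X = np.random.default_rng(1).normal(size=(4, 2))
        h, c, _ = lstm_forward(X, p)
        # zero weights: candidate σ(0)=0.5, input gate 0.5 → c grows
        assert c[-1].sum() != 0.0


class TestLSTMLoss:
    def test_certain_correct_prediction_zero_loss(self):
        assert lstm_loss(np.array([[0.0, 1.0, 0.0]]), np.array([1])) == pytest.approx(0.0)

    def test_uniform_prediction_log_k(self):
        probs = np.full((1, 4), 0.25)
        assert lstm_loss(probs, np.array([2])) == pytest.approx(math.log(4))

    def test_batch_loss_is_mean_of_singles(self):
        p1 = np.array([[0.7, 0.3]])
        p2 = np.array([[0.2, 0.8]])
        both = np.vstack([p1, p2])
        single = (lstm_loss(p1, np.array([0])) + lstm_loss(p2, np.array([1]))) / 2
        assert lstm_loss(both, np.array([0, 1])) == pytest.approx(single)


class TestLSTMTraining:
    def test_bptt_gradients_match_finite_differences(self):
        p = init_params(2, 3, np.arange(4), seed=1, scale=0.5)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3, 2))
        y = np.array([0, 1, 2, 3])
        _, _, probs, cache = lstm_forward(X, p, return_cache=True)
        grads = lstm_backward(p, cache, probs, y)
        eps, worst = 1e-6, 0.0
        for arr, g in zip(p.flat(), grads):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                _, _, pp = lstm_forward(X, p)
                arr[ix] = orig - eps
                _, _, pm = lstm_forward(X, p)
                arr[ix] = orig
                num = (lstm_loss(pp, y) - lstm_loss(pm, y)) / (2 * eps)
                denom = max(1e-8, abs(num) + abs(g[ix]))
                worst = max(worst, abs(num - g[ix]) / denom)
        assert worst < 1e-4

    def test_toy_sequence_task_converges(self):
        rng = np.random.default_rng(4)
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.normal(0, 0.3, (n, 3, 2)) + y[:, None, None] * 2.0
        fit = train_lstm(X, y, TrainConfig(hidden_size=4, epochs=30,
                                           learning_rate=0.02, seed=0))
        assert fit.loss_history[-1] < 0.1 * fit.loss_history[0]

    def test_training_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 2, 2))
        y = rng.integers(0, 2, 60)
        cfg = TrainConfig(hidden_size=3, epochs=5, seed=9)
        f1 = train_lstm(X, y, cfg)
        f2 = train_lstm(X, y, cfg)
        assert f1.loss_history == f2.loss_history
        assert f1.params.wx == pytest.approx(f2.params.wx)

    def test_divergence_aborts_with_diagnostics(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2, 2)) * 50
        y = rng.integers(0, 2, 40)
        cfg = TrainConfig(hidden_size=4, epochs=60, learning_rate=5.0,
                          seed=0, divergence_factor=1.5)
        with pytest.raises(RuntimeError, match="diverged"):
            train_lstm(X, y, cfg)


class TestSweepAndSequence:
    def test_single_ns_sweep_yields_one_report(self, feature_pool):
        cfg = TrainConfig(hidden_size=4, epochs=3, learning_rate=0.02, seed=0)
        res = memory_sweep(feature_pool, [1], cfg)
        assert len(res.reports) == 1 and res.best_ns == 1

    def test_perfect_oracle_model_reproduces_hypnogram(self, one_night):
        table = ws.night_feature_table(one_night)

        class Oracle:
            def __init__(self, stages, ns):
                self.stages, self.ns = stages, ns

            def predict(self, X):
                return self.stages[self.ns :][: len(X)]

        stages = table.frame["stage"].to_numpy()
        pred = predict_sequence(Oracle(stages, 2), table, 2)
        rep = ws.score(stages[: len(pred)], pred.frame["stage"].to_numpy())
        assert rep.accuracy == 1.0 and rep.cohen_kappa == 1.0

    def test_constant_predictor_has_zero_kappa_on_balanced_truth(self):
        y_true = np.repeat(["w", "x", "y", "z"], 25)
        y_pred = np.array(["w"] * 100)
        rep = ws.score(y_true, y_pred)
        assert rep.accuracy == pytest.approx(0.25)
        assert rep.cohen_kappa == pytest.approx(0.0)

    def test_trained_rf_transition_count_same_order_as_truth(self, feature_pool):
        # context-aware RF (ns=8) rolled over a held-out night: the
        # predicted hypnogram may flicker, but not wildly more than truth
        ns = 8
        night_cfg = ws.GeneratorConfig(seed=77, epoch_interval=60)
        night = ws.generate_nights(night_cfg, 1, seed=77)[0]
        table = ws.night_feature_table(night)
        ds = make_windows(feature_pool, ns)
        clf = fit_memoryless(ds.X.reshape(len(ds.X), -1), ds.y, "RF", grid={})
        pred = predict_sequence(clf, table, ns)
        def transitions(stages):
            s = np.asarray(stages)
            return int((s[1:] != s[:-1]).sum())
        t_true = transitions(table.frame["stage"])
        t_pred = transitions(pred.frame["stage"])
        assert t_pred <= 3 * t_true
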