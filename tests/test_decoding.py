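"""State resampling and the softmax network decoder."""
import numpy as np
import pandas as pd
import pytest

import crossreact as cr
from crossreact import decoding as dec
from crossreact.config import EpochWindow
from crossreact.encoding import epoch_mean
from crossreact.errors import AnalysisError

from conftest import flat_trials, make_tensor


def separable_states(n_per_class=40, n_features=25, gap=4.0, seed=0,
                     k=5):
    rng = np.random.default_rng(seed)
    X, y = [], []
    centers = rng.normal(scale=gap, size=(k, n_features))
    for c in range(k):
        X.append(centers[c] + rng.normal(size=(n_per_class, n_features)) * 0.3)
        y.append(np.full(n_per_class, c + 1))
    return np.vstack(X), np.concatenate(y)


class TestBuildStates:
    @pytest.fixture(scope="class")
    def tensor_and_trials(self):
        trials = flat_trials(60)
        rng = np.random.default_rng(90)
        rate = rng.normal(size=(12, 60, 200)).astype(np.float32)
        return make_tensor(rate, trials), trials

    def test_vector_length_and_labels(self, tensor_and_trials):
        rt, trials = tensor_and_trials
        win = EpochWindow("w", "offer2_on", 0, 100)
        ss = dec.build_states(rt, trials, win, "described", n_states=50, seed=0)
        assert ss.X.shape == (50, 12)
        assert sorted(np.unique(ss.y)) == [1, 2, 3, 4, 5]
        assert np.bincount(ss.y)[1:].tolist() == [10] * 5

    def test_seed_determinism(self, tensor_and_trials):
        rt, trials = tensor_and_trials
        win = EpochWindow("w", "offer2_on", 0, 100)
        a = dec.build_states(rt, trials, win, "described", 50, seed=3)
        b = dec.build_states(rt, trials, win, "described", 50, seed=3)
        c = dec.build_states(rt, trials, win, "described", 50, seed=4)
        assert np.array_equal(a.X, b.X)
        assert not np.array_equal(a.X, c.X)

    def test_resampling_mean_matches_group_mean(self, tensor_and_trials):
        # oracle: with many replicates, the average state converges on the
        # direct group-mean epoch rate
        rt, trials = tensor_and_trials
        win = EpochWindow("w", "offer2_on", 0, 100)
        ss = dec.build_states(rt, trials, win, "described", 5000, seed=5)
        em = epoch_mean(rt, trials[trials.trial_type == "described"], win)
        sizes = np.sort(trials["offer1_size"].unique())
        sub = trials[trials.trial_type == "described"].reset_index()
        for ci, size in enumerate(sizes):
            grp = np.where(sub["offer1_size"] == size)[0]
            direct = em[grp].mean(axis=0)
            resampled = ss.X[ss.y == ci + 1].mean(axis=0)
            sd = em[grp].std(axis=0) / np.sqrt(1000) + 1e-12
            assert np.all(np.abs(resampled - direct) < 6 * sd + 0.05)

    def test_empty_majority_groups_error(self, tensor_and_trials):
        rt, trials = tensor_and_trials
        win = EpochWindow("w", "offer2_on", 0, 100)
        starved = trials.copy()
        never_chosen = starved["offer1_size"].isin([75.0, 100.0, 150.0])
        starved.loc[never_chosen, "chosen_option"] = 2
        starved.loc[never_chosen, "chosen_size"] = starved.loc[never_chosen,
                                                               "offer2_size"]
        with pytest.raises(AnalysisError, match="more trials"):
            dec.build_states(rt, starved, win, "described", 50, seed=0,
                             selection="offer1-chosen")


class TestSoftmaxDecoder:
    def test_softmax_outputs_sum_to_one(self):
        rng = np.random.default_rng(100)
        m = dec.SoftmaxDecoder(n_hidden=8, n_epochs=2, random_state=0)
        X, y = separable_states(10, 12, seed=1)
        m.fit(X, y)
        p = m.predict_proba(rng.normal(size=(20, 12)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_gradient_matches_finite_differences(self):
        # oracle equivalence: analytic gradient of the per-sample
        # log-likelihood vs central differences
        rng = np.random.default_rng(101)
        W1 = rng.uniform(-0.01, 0.01, (7, 10))
        W2 = rng.uniform(-0.01, 0.01, (5, 7))
        x = rng.normal(size=10)
        code = 2
        _, g1, g2 = dec.loglik_and_grads(W1, W2, x, code)
        eps = 1e-6
        for W, g in ((W1, g1), (W2, g2)):
            idx = [(0, 0), (1, 3), (W.shape[0] - 1, W.shape[1] - 1)]
            for i, j in idx:
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                lp = dec.loglik_and_grads(Wp if W is W1 else W1,
                                          Wp if W is W2 else W2, x, code)[0]
                lm = dec.loglik_and_grads(Wm if W is W1 else W1,
                                          Wm if W is W2 else W2, x, code)[0]
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[i, j]) / max(abs(fd), 1e-8) < 1e-4

    def test_learns_separable_classes(self):
        X, y = separable_states(40, 25, seed=2)
        m = dec.SoftmaxDecoder(n_epochs=200, random_state=1).fit(X, y)
        assert (m.predict(X) == y).mean() >= 0.95
        # loss trend decreases
        assert m.loss_history_[-1] < m.loss_history_[0] / 5

    def test_label_shuffle_gives_chance(self):
        rng = np.random.default_rng(102)
        X, y = separable_states(40, 25, seed=3)
        tr = rng.permutation(200)[:150]
        te = np.setdiff1d(np.arange(200), tr)
        y_shuf = rng.permutation(y[tr])
        m = dec.SoftmaxDecoder(n_epochs=150, random_state=2).fit(X[tr], y_shuf)
        acc = 100 * (m.predict(X[te]) == y[te]).mean()
        lo, hi = dec.chance_band(len(te))
        assert lo <= acc <= hi

    def test_nan_input_rejected(self):
        X, y = separable_states(5, 4, seed=4)
        X[0, 0] = np.nan
        with pytest.raises(AnalysisError):
            dec.SoftmaxDecoder(n_epochs=1).fit(X, y)

    def test_sklearn_param_interface(self):
        m = dec.SoftmaxDecoder(n_hidden=13)
        assert m.get_params()["n_hidden"] == 13
        m.set_params(learning_rate=0.01)
        assert m.learning_rate == 0.01


class TestCrossDecode:
    def test_train_equals_test_is_near_perfect(self):
        X, y = separable_states(25, 20, seed=5)
        ss = dec.StateSet(X, y, "offer1", "described", np.arange(5))
        res = dec.cross_decode(ss, ss, decoder="mlp", n_epochs=200, seed=0)
        assert res.accuracy >= 99.0
        assert res.confusion.sum() == len(y)
        assert np.array_equal(res.confusion.sum(axis=1),
                              np.bincount(y)[1:])

    def test_within_condition_folds(self):
        X, y = separable_states(20, 20, seed=6)
        ss = dec.StateSet(X, y, "offer1", "described", np.arange(5))
        res = dec.cross_decode(ss, None, folds=4, decoder="margin", seed=1)
        assert len(res.fold_accuracies) == 4
        assert res.n == 100
        assert res.accuracy > 90.0

    def test_neuron_permutation_invariance_margin(self):
        # common reordering of features in train and test leaves accuracy
        # unchanged for a deterministic decoder
        X, y = separable_states(20, 20, seed=7, gap=1.0)
        Xt, yt = separable_states(20, 20, seed=8, gap=1.0)
        perm = np.random.default_rng(9).permutation(20)
        a = dec.StateSet(X, y, "a", "d", np.arange(5))
        b = dec.StateSet(Xt, yt, "b", "d", np.arange(5))
        ap = dec.StateSet(X[:, perm], y, "a", "d", np.arange(5))
        bp = dec.StateSet(Xt[:, perm], yt, "b", "d", np.arange(5))
        r1 = dec.cross_decode(a, b, decoder="margin", seed=2)
        r2 = dec.cross_decode(ap, bp, decoder="margin", seed=2)
        assert r1.accuracy == pytest.approx(r2.accuracy)

    def test_margin_agrees_on_separable(self):
        X, y = separable_states(20, 20, seed=10)
        ss = dec.StateSet(X, y, "offer1", "described", np.arange(5))
        res = dec.margin_decode(ss, ss, seed=0)
        assert res.accuracy >= 99.0

    def test_dimension_mismatch_rejected(self):
        X, y = separable_states(5, 10, seed=11)
        X2, y2 = separable_states(5, 12, seed=11)
        a = dec.StateSet(X, y, "a", "d", np.arange(5))
        b = dec.StateSet(X2, y2, "b", "d", np.arange(5))
        with pytest.raises(AnalysisError):
            dec.cross_decode(a, b, decoder="margin", seed=0)


class TestSlidingDecode:
    def test_signal_confined_to_planted_window(self):
        # rates carry class information only inside [0, 100) after offer2_on
        trials = flat_trials(100)
        rng = np.random.default_rng(110)
        rate = rng.normal(size=(15, 100, 200)).astype(np.float32)
        sizes = trials["offer1_size"].to_numpy()
        w = rng.normal(scale=1.5, size=15)
        b0 = int((400.0 + 0.0) / 10)
        rate[:, :, b0:b0 + 10] += np.outer(
            w, (sizes - sizes.mean()) / sizes.std()).T.reshape(15, 100, 1).transpose(0, 1, 2)
        rt = make_tensor(rate, trials)
        win = EpochWindow("w", "offer2_on", 0, 100)
        ss = dec.build_states(rt, trials, win, "described", 100, seed=0)
        m = dec.SoftmaxDecoder(n_epochs=200, random_state=0).fit(ss.X, ss.y)
        out = dec.sliding_decode(m, rt, trials, "described", "offer2_on",
                                 (-400, 500), window_ms=100.0, step_ms=100.0,
                                 n_states=100, seed=1)
        lo, hi = dec.chance_band(100)
        on_target = out.loc[out.center_ms == 50.0, "accuracy"].iloc[0]
        pre = out[out.center_ms < -50]["accuracy"]
        assert on_target > hi
        assert (pre <= hi).all()
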