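"""Population-state resampling and cross-epoch decoding.

A population activation state is a pseudo-population vector: one trial is
drawn (with replacement) per condition group independently for every neuron,
and that trial's mean normalized rate over the epoch window fills the
neuron's entry. The decoder is a three-layer softmax network (input =
n_neurons, 40 logistic hidden units, 5 softmax outputs, no biases) trained
by stochastic gradient ascent on the multinomial log-likelihood with
learning rate 0.005 for 1000 sweeps — implemented from scratch because this
exact recipe (initialization, update rule, schedule) is part of the method
under study. A standard maximum-margin (SVM/one-vs-rest) decoder is provided
as an independent cross-check.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .behavior import gof_chisq, ProportionTestResult
from .config import EpochWindow
from .encoding import RateTensor, epoch_mean, select_trials
from .errors import AnalysisError

__all__ = ["StateSet", "build_states", "SoftmaxDecoder", "DecodeResult",
           "cross_decode", "transfer_decode", "sliding_decode", "margin_decode",
           "chance_band", "loglik_and_grads"]


@dataclass
class StateSet:
    """Resampled population activation states for one epoch x trial type."""

    X: np.ndarray  # (n_states, n_neurons)
    y: np.ndarray  # size class 1..k
    epoch: str
    trial_type: str
    class_sizes: np.ndarray  # µl per class label
    imputed_classes: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)


def build_states(rt: RateTensor, trials: pd.DataFrame, window: EpochWindow,
                 trial_type: str, n_states: int = 500, seed=None,
                 selection: str = "all", size_column: str = "offer1_size") -> StateSet:
    """Resample ``n_states`` pseudo-population states for one condition.

    Trials of the requested type are grouped by offer-1 size; each state
    draws one trial per group per neuron independently, with replacement,
    and averages its z-scored rates over the window. ``n_states`` must be a
    multiple of the number of size classes. For the outcome epoch pass
    ``selection='offer1-chosen'`` so the delivered reward equals the offer-1
    size. A group with no trials at all is imputed at 0 (the z-scored mean)
    and recorded in ``imputed_classes``.
    """
    rng = np.random.default_rng(seed)
    sub = select_trials(trials, trial_type, selection)
    sizes = np.sort(trials[size_column].unique())
    k = len(sizes)
    if n_states % k:
        raise AnalysisError(f"n_states must be a multiple of {k}")
    reps = n_states // k

    em = None
    if len(sub):
        em = epoch_mean(rt, sub, window)  # (T_sel, N)
    n_neurons = rt.rate.shape[0]
    X = np.zeros((n_states, n_neurons))
    y = np.repeat(np.arange(1, k + 1), reps)
    imputed = []
    pos = {t: i for i, t in enumerate(sub["trial_id"].to_numpy())}
    for ci, size in enumerate(sizes):
        ids = sub.loc[sub[size_column] == size, "trial_id"].to_numpy()
        rows = slice(ci * reps, (ci + 1) * reps)
        if len(ids) == 0:
            imputed.append(int(ci + 1))
            continue
        g_idx = np.asarray([pos[t] for t in ids])
        draws = rng.integers(0, len(g_idx), size=(reps, n_neurons))
        X[rows] = em[g_idx[draws], np.arange(n_neurons)[None, :]]
    if len(imputed) > k // 2:
        raise AnalysisError(
            f"{len(imputed)} of {k} size groups empty under selection "
            f"{selection!r}; collect more trials")
    # states are emitted in label order; interleave deterministically so that
    # contiguous CV folds stay class-balanced
    order = np.arange(n_states).reshape(k, reps).T.ravel()
    return StateSet(X[order], y[order], window.name, trial_type, sizes, imputed)


def loglik_and_grads(W1: np.ndarray, W2: np.ndarray, x: np.ndarray, code: int):
    """Per-sample log-likelihood and its gradients for the softmax network.

    Forward: h = logistic(W1 x), y = softmax(W2 h); returns
    (log y[code], dlogL/dW1, dlogL/dW2). This is the exact quantity the
    training loop ascends, so it is what the finite-difference check probes.
    """
    h = expit(W1 @ x)
    s = W2 @ h
    e = np.exp(s - s.max())
    y = e / e.sum()
    d2 = -y
    d2[code] += 1.0  # delta_kp - y_k
    d1 = (W2.T @ d2) * h * (1.0 - h)
    return np.log(max(y[code], 1e-300)), np.outer(d1, x), np.outer(d2, h)


class SoftmaxDecoder(BaseEstimator, ClassifierMixin):
    """Three-layer softmax network trained by per-sample gradient ascent.

    Forward pass: hidden ``h = logistic(W1 x)``, output ``y = softmax(W2 h)``;
    no bias terms. Training maximizes the multinomial log-likelihood with
    per-sample updates ``W += lr * dlogL/dW`` in a freshly shuffled order
    each sweep; weights start uniform on (-init_scale, +init_scale). No
    momentum, regularization, or early stopping.

    Parameters follow the printed recipe: 40 hidden units, learning rate
    0.005, 1000 sweeps, init scale 0.01.
    """

    def __init__(self, n_hidden: int = 40, learning_rate: float = 0.005,
                 n_epochs: int = 1000, init_scale: float = 0.01,
                 random_state=None):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.init_scale = init_scale
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise AnalysisError("X must be 2-D and aligned with y")
        if np.isnan(X).any():
            raise AnalysisError("NaN in decoder inputs")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise AnalysisError("need at least 2 classes")
        codes = np.searchsorted(self.classes_, y)
        n, d = X.shape
        k = len(self.classes_)
        rng = np.random.default_rng(self.random_state)
        self.W1_ = rng.uniform(-self.init_scale, self.init_scale, (self.n_hidden, d))
        self.W2_ = rng.uniform(-self.init_scale, self.init_scale, (k, self.n_hidden))
        lr = self.learning_rate
        loss_history = np.empty(self.n_epochs)
        rising = 0
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            nll = 0.0
            for i in order:
                logp, g1, g2 = loglik_and_grads(self.W1_, self.W2_, X[i], codes[i])
                nll -= logp
                self.W1_ += lr * g1
                self.W2_ += lr * g2
            loss_history[epoch] = nll / n
            if epoch and loss_history[epoch] > loss_history[epoch - 1]:
                rising += 1
                if rising >= 10:
                    warnings.warn("training loss rose 10 consecutive sweeps")
                    rising = 0
            else:
                rising = 0
        self.loss_history_ = loss_history
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=float)
        H = expit(X @ self.W1_.T)
        return softmax(H @ self.W2_.T, axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def log_likelihood(self, X, y):
        """Mean log-likelihood of labels; used by the gradient check."""
        p = self.predict_proba(X)
        codes = np.searchsorted(self.classes_, np.asarray(y))
        return float(np.mean(np.log(p[np.arange(len(y)), codes])))


@dataclass
class DecodeResult:
    accuracy: float  # percent
    confusion: np.ndarray  # (k, k) rows = true class
    n: int
    chisq: ProportionTestResult
    train_condition: str
    test_condition: str
    fold_accuracies: list
    decoder: str
    chance: float = 20.0

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "confusion": self.confusion.tolist(),
                "n": self.n, "chisq": self.chisq.to_dict(),
                "train_condition": self.train_condition,
                "test_condition": self.test_condition,
                "fold_accuracies": self.fold_accuracies,
                "decoder": self.decoder, "chance": self.chance}


def chance_band(n: int, k_classes: int = 5, level: float = 0.95):
    """Two-sided binomial band (percent) around chance for n test states."""
    from scipy import stats as st
    p0 = 1.0 / k_classes
    lo = st.binom.ppf((1 - level) / 2, n, p0) / n
    hi = st.binom.ppf(1 - (1 - level) / 2, n, p0) / n
    return 100.0 * lo, 100.0 * hi


def _evaluate(model, X, y, k: int) -> tuple[int, np.ndarray]:
    pred = model.predict(X)
    correct = int((pred == y).sum())
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        conf[int(t) - 1, int(p) - 1] += 1
    return correct, conf


def _make_decoder(decoder: str, seed, **mlp_kwargs):
    if decoder == "mlp":
        return SoftmaxDecoder(random_state=seed, **mlp_kwargs)
    if decoder == "margin":
        return OneVsRestClassifier(LinearSVC(random_state=int(seed) % (2**31)
                                             if seed is not None else None))
    raise AnalysisError(f"unknown decoder {decoder!r}")


def cross_decode(train: StateSet, test: StateSet | None = None, folds: int = 4,
                 seed=None, decoder: str = "mlp", chance: float | None = None,
                 **mlp_kwargs) -> DecodeResult:
    """Within-condition k-fold decoding, or cross-condition transfer.

    With ``test=None`` the states are split into ``folds`` shuffled folds
    (375 train / 125 test at the defaults) and the reported accuracy is the
    mean over folds with a pooled confusion matrix. With a second condition
    the decoder is trained on every state of ``train`` and tested on every
    state of ``test`` (the samples share nothing, so no folding is needed).
    Significance is a one-sided goodness-of-fit chi-square of the correct
    count against chance (1/k).
    """
    k = len(np.unique(train.y))
    if chance is None:
        chance = 100.0 / k
    rng = np.random.default_rng(seed)
    if test is not None and test.X.shape[1] != train.X.shape[1]:
        raise AnalysisError("train/test state dimensionality mismatch")

    fold_accs: list[float] = []
    if test is None:
        n = len(train)
        order = rng.permutation(n)
        fold_ids = np.arange(n) % folds
        correct_total = 0
        conf = np.zeros((k, k), dtype=int)
        for f in range(folds):
            te = order[fold_ids == f]
            tr = order[fold_ids != f]
            model = _make_decoder(decoder, rng.integers(2**31), **mlp_kwargs)
            model.fit(train.X[tr], train.y[tr])
            c, cf = _evaluate(model, train.X[te], train.y[te], k)
            fold_accs.append(100.0 * c / len(te))
            correct_total += c
            conf += cf
        n_tested = n
        label_tr = label_te = f"{train.epoch}/{train.trial_type}"
    else:
        model = _make_decoder(decoder, rng.integers(2**31), **mlp_kwargs)
        model.fit(train.X, train.y)
        correct_total, conf = _evaluate(model, test.X, test.y, k)
        n_tested = len(test)
        label_tr = f"{train.epoch}/{train.trial_type}"
        label_te = f"{test.epoch}/{test.trial_type}"
    acc = 100.0 * correct_total / n_tested
    chi = gof_chisq(correct_total, n_tested, chance / 100.0, sided="greater")
    return DecodeResult(acc, conf, n_tested, chi, label_tr, label_te,
                        fold_accs, decoder, chance)


def transfer_decode(model, train: StateSet, test: StateSet,
                    decoder: str = "mlp", chance: float | None = None) -> DecodeResult:
    """Evaluate an already-fitted decoder on another condition's states."""
    if test.X.shape[1] != train.X.shape[1]:
        raise AnalysisError("train/test state dimensionality mismatch")
    k = len(np.unique(train.y))
    if chance is None:
        chance = 100.0 / k
    correct, conf = _evaluate(model, test.X, test.y, k)
    n = len(test)
    chi = gof_chisq(correct, n, chance / 100.0, sided="greater")
    return DecodeResult(100.0 * correct / n, conf, n, chi,
                        f"{train.epoch}/{train.trial_type}",
                        f"{test.epoch}/{test.trial_type}", [], decoder, chance)


def sliding_decode(model, rt: RateTensor, trials: pd.DataFrame,
                   trial_type: str, align_event: str,
                   span_ms: tuple[float, float], window_ms: float = 300.0,
                   step_ms: float = 100.0, n_states: int = 100, seed=None,
                   selection: str = "all") -> pd.DataFrame:
    """Evaluate a trained decoder on states rebuilt in sliding windows.

    Returns one row per window center: center_ms, accuracy (percent), n.
    """
    rng = np.random.default_rng(seed)
    rows = []
    centers = np.arange(span_ms[0] + window_ms / 2,
                        span_ms[1] - window_ms / 2 + 1e-9, step_ms)
    for c in centers:
        win = EpochWindow("sliding", align_event, c - window_ms / 2,
                          c + window_ms / 2)
        ss = build_states(rt, trials, win, trial_type, n_states=n_states,
                          seed=rng.integers(2**31), selection=selection)
        pred = model.predict(ss.X)
        rows.append({"center_ms": float(c),
                     "accuracy": 100.0 * float((pred == ss.y).mean()),
                     "n": len(ss)})
    return pd.DataFrame(rows)


def margin_decode(train: StateSet, test: StateSet | None = None,
                  folds: int = 4, seed=None) -> DecodeResult:
    """Maximum-margin (linear SVM, one-vs-rest) counterpart of cross_decode."""
    return cross_decode(train, test, folds=folds, seed=seed, decoder="margin")
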