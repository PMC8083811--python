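"""Short-phrase category classifier: a bidirectional LSTM over frozen
word embeddings.

Architecture (three layers): an embedding layer mapping token ids to
pre-trained word vectors (row 0 reserved for padding, frozen by
default), a bidirectional LSTM with 64 hidden units per direction and
input dropout 0.5, and a dense output layer with one *logistic* unit
per category.  The output scores are independent sigmoids and need not
sum to one; training nevertheless uses categorical cross-entropy, i.e.
the sigmoids are normalized to a distribution inside the loss only, so
the loss is ``-log(sigma_true / sum_c sigma_c)``.

Training runs a single epoch of Adam (lr 0.001, batch 100) by default.
Because only one pass is made over the data, the dense head is
initialized at zero: every category starts at score 0.5 and the head's
first gradient steps are already aligned with the recurrent features,
which makes one-epoch training effective.  Recurrent kernels are
orthogonal, input kernels Glorot-uniform, and the forget-gate bias
starts at 1.

The implementation is pure numpy (forward pass, backpropagation through
time, Adam); gradient correctness is checked against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .corpus import PAD_ID, CorpusSplit
from .embedding import EmbeddingModel

__all__ = ["BiLSTMClassifier", "ClassifierMetrics", "evaluate_classifier",
           "train_classifier"]

_EPS = 1e-7  # loss clipping, matching common deep-learning defaults


@dataclass
class ClassifierMetrics:
    """Multi-class evaluation summary of the phrase classifier."""

    accuracy: float
    precision_micro: float
    recall_micro: float
    f1_micro: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_category_auroc: dict = field(default_factory=dict)
    micro_average_auroc: float = float("nan")
    confusion: np.ndarray | None = None  # rows = truth (fractions)


def _glorot_uniform(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng, n):
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class _LSTMDirection:
    """Parameters and forward/backward pass of one LSTM direction.

    The input kernel is initialized for unit-variance gate
    preactivations given the *empirical* component scale of the word
    vectors (``input_scale``): pre-trained embeddings are typically
    near-unit-norm, so their per-component variance is ~1/dim — far
    below the unit variance Glorot assumes — and an unscaled init
    leaves the recurrent layer in a near-linear dead zone that a single
    training epoch cannot escape.
    """

    def __init__(self, rng, dim, hidden, input_scale=1.0):
        self.dim, self.hidden = dim, hidden
        H = hidden
        limit = np.sqrt(3.0) / (input_scale * np.sqrt(dim))
        self.Wx = rng.uniform(-limit, limit, size=(dim, 4 * H))
        self.Wh = np.hstack([_orthogonal(rng, H) for _ in range(4)])
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # unit forget-gate bias

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, cache=None):
        """Run over time; x is (B, T, dim). Returns final hidden state.

        When *cache* is a list the per-step activations are stored for
        backpropagation; otherwise only the state is propagated.
        """
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = expit(z[:, :H])
            f = expit(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = expit(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t] = h
            if cache is not None:
                cache.append((x[:, t], h_prev, c_prev, i, f, g, o, tc))
        return h, hs

    def backward(self, cache, dh_steps):
        """BPTT. *dh_steps* is (B, T, H) external gradient on each h_t.

        Returns (dWx, dWh, db, dx) with dx shaped like the input.
        """
        T = len(cache)
        H = self.hidden
        B = dh_steps.shape[0]
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty((B, T, self.dim))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dh_next + dh_steps[:, t]
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dWx, dWh, db, dx


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class BiLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Bidirectional-LSTM classifier of short metadata phrases.

    Parameters
    ----------
    embedding : EmbeddingModel
        Pre-trained token vectors; copied into the (frozen by default)
        embedding layer with a zero row prepended for padding.
    hidden_units : int, default 64
        LSTM units per direction.
    dropout : float, default 0.5
        Input dropout of the recurrent layer during training.
    max_len : int, default 7
        Sequence length; inputs are right-padded token-id rows.
    n_categories : int
        Number of output categories (>= 2).
    learning_rate, batch_size, epochs
        Adam step size (0.001), mini-batch size (100), passes (1).
    trainable_embedding : bool, default False
        Whether gradient flows into the embedding matrix.
    output_mode : {"final", "mean"}, default "final"
        Use the concatenated final states of both directions, or the
        time-mean of the concatenated hidden states.
    random_state : int or None
        Seed for initialization, shuffling and dropout masks.

    Attributes
    ----------
    classes_ : ndarray of category indices.
    training_log_ : list of per-batch mean losses.
    baseline_scores_ : score vector of the all-padding input ("empty
        string"), used downstream as the uninformative baseline.
    """

    def __init__(self, embedding=None, hidden_units=64, dropout=0.5,
                 max_len=7, n_categories=None, learning_rate=0.001,
                 batch_size=100, epochs=1, trainable_embedding=False,
                 output_mode="final", random_state=None):
        self.embedding = embedding
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.max_len = max_len
        self.n_categories = n_categories
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.trainable_embedding = trainable_embedding
        self.output_mode = output_mode
        self.random_state = random_state

    # -- construction -----------------------------------------------------

    def _build(self, rng, n_categories, E=None):
        if n_categories < 2:
            raise ValueError("need at least 2 categories")
        if E is None:
            if self.embedding is None:
                raise ValueError("an EmbeddingModel (or saved weights) is required")
            V, d = self.embedding.vectors.shape
            E = np.vstack([np.zeros((1, d)), self.embedding.vectors])
        d = E.shape[1]
        H = self.hidden_units
        self._E = E.astype(np.float64)
        # empirical per-component RMS of the (non-padding) word vectors
        scale = float(np.sqrt(np.mean(self._E[1:] ** 2))) or 1.0
        self._fwd = _LSTMDirection(rng, d, H, input_scale=scale)
        self._bwd = _LSTMDirection(rng, d, H, input_scale=scale)
        self._Wd = np.zeros((2 * H, n_categories))
        self._bd = np.zeros(n_categories)
        self.classes_ = np.arange(n_categories)
        self.n_categories_ = n_categories

    # -- forward ----------------------------------------------------------

    def _forward(self, X, training=False, rng=None, caches=None):
        X = np.asarray(X, dtype=np.int64)
        x = self._E[X]  # (B, T, d)
        masks = []
        xs = []
        for _ in range(2):
            if training and self.dropout > 0:
                mask = (rng.random((x.shape[0], 1, x.shape[2])) >= self.dropout)
                mask = mask / (1.0 - self.dropout)
            else:
                mask = None
            masks.append(mask)
            xs.append(x if mask is None else x * mask)
        cf = [] if caches is not None else None
        cb = [] if caches is not None else None
        _, hsf = self._fwd.forward(xs[0], cf)
        hb, hsb = self._bwd.forward(xs[1][:, ::-1], cb)
        # Final states are read at the sequence ends of the *real* tokens:
        # the backward pass sees trailing pads first (zero input keeps its
        # state at zero), so its last step is already clean; the forward
        # state is gathered at the last non-padding position, since letting
        # it coast through trailing pads dilutes short phrases.
        n_real = (X != PAD_ID).sum(axis=1)
        last = np.maximum(n_real - 1, 0)
        rows = np.arange(X.shape[0])
        hf = np.where((n_real > 0)[:, None], hsf[rows, last], 0.0)
        if self.output_mode == "mean":
            u = np.concatenate([hsf.mean(axis=1), hsb.mean(axis=1)], axis=1)
        else:
            u = np.concatenate([hf, hb], axis=1)
        z = u @ self._Wd + self._bd
        p = expit(z)
        if caches is not None:
            caches.update(X=X, masks=masks, cf=cf, cb=cb, u=u, p=p,
                          T=X.shape[1], last=last, n_real=n_real)
        return p

    @staticmethod
    def _loss_and_dz(p, y):
        """Categorical cross-entropy over sum-normalized sigmoids."""
        B, C = p.shape
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        S = pc.sum(axis=1, keepdims=True)
        q = pc / S
        loss = -np.log(q[np.arange(B), y]).mean()
        Y = np.zeros_like(p)
        Y[np.arange(B), y] = 1.0
        dz = (pc * (1 - pc) / S - Y * (1 - pc)) / B
        return loss, dz

    def _backward(self, caches, dz):
        H = self.hidden_units
        T = caches["T"]
        du = dz @ self._Wd.T
        dWd = caches["u"].T @ dz
        dbd = dz.sum(axis=0)
        B = dz.shape[0]
        dh_f = np.zeros((B, T, H))
        dh_b = np.zeros((B, T, H))
        if self.output_mode == "mean":
            dh_f += du[:, None, :H] / T
            dh_b += du[:, None, H:] / T
        else:
            rows = np.arange(B)
            present = (caches["n_real"] > 0)[:, None]
            dh_f[rows, caches["last"]] = du[:, :H] * present
            dh_b[:, -1] = du[:, H:]
        dWx_f, dWh_f, db_f, dx_f = self._fwd.backward(caches["cf"], dh_f)
        dWx_b, dWh_b, db_b, dx_b = self._bwd.backward(caches["cb"], dh_b)
        dx_b = dx_b[:, ::-1]
        grads = [dWx_f, dWh_f, db_f, dWx_b, dWh_b, db_b, dWd, dbd]
        dE = None
        if self.trainable_embedding:
            dE = np.zeros_like(self._E)
            for k, dx in ((0, dx_f), (1, dx_b)):
                mask = caches["masks"][k]
                if mask is not None:
                    dx = dx * mask
                np.add.at(dE, caches["X"], dx)
            dE[PAD_ID] = 0.0  # the padding row stays zero
        return grads, dE

    # -- sklearn surface --------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or X.shape[1] != self.max_len:
            raise ValueError(f"X must be (n_samples, {self.max_len}) token ids")
        if len(X) == 0:
            raise ValueError("training set is empty")
        n_cat = self.n_categories or int(y.max()) + 1
        if y.min() < 0 or y.max() >= n_cat:
            raise ValueError("labels must be in [0, n_categories)")
        rng = np.random.default_rng(self.random_state)
        self._build(rng, n_cat)
        params = (self._fwd.params() + self._bwd.params()
                  + [self._Wd, self._bd])
        opt = _Adam(params, self.learning_rate)
        opt_E = _Adam([self._E], self.learning_rate) if self.trainable_embedding else None
        self.training_log_ = []
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                caches: dict = {}
                p = self._forward(X[idx], training=True, rng=rng, caches=caches)
                loss, dz = self._loss_and_dz(p, y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                self.training_log_.append(float(loss))
                grads, dE = self._backward(caches, dz)
                opt.step(grads)
                if dE is not None:
                    opt_E.step([dE])
        self.baseline_scores_ = self.score_tokens(
            np.full(self.max_len, PAD_ID, dtype=np.int64))
        return self

    def predict_proba(self, X):
        """Per-category logistic scores in [0, 1].

        These are independent sigmoid outputs and deliberately do not
        sum to one across categories.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=np.int64)
        out = np.empty((len(X), self.n_categories_))
        for start in range(0, len(X), 4096):
            out[start:start + 4096] = self._forward(X[start:start + 4096])
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score_tokens(self, token_ids) -> np.ndarray:
        """Score vector of a single padded token-id row."""
        return self._forward(np.asarray(token_ids, dtype=np.int64)[None, :])[0]

    def _check_fitted(self):
        if not hasattr(self, "classes_"):
            raise RuntimeError("classifier is not fitted")

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        cfg = {k: v for k, v in self.get_params().items() if k != "embedding"}
        np.savez(
            path,
            config=json.dumps(cfg),
            E=self._E,
            Wx_f=self._fwd.Wx, Wh_f=self._fwd.Wh, b_f=self._fwd.b,
            Wx_b=self._bwd.Wx, Wh_b=self._bwd.Wh, b_b=self._bwd.b,
            Wd=self._Wd, bd=self._bd,
            baseline=self.baseline_scores_,
            training_log=np.array(self.training_log_),
        )

    @classmethod
    def load(cls, path) -> "BiLSTMClassifier":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["config"]))
            clf = cls(**cfg)
            rng = np.random.default_rng(0)
            clf._build(rng, cfg["n_categories"], E=data["E"])
            clf._fwd.Wx, clf._fwd.Wh, clf._fwd.b = data["Wx_f"], data["Wh_f"], data["b_f"]
            clf._bwd.Wx, clf._bwd.Wh, clf._bwd.b = data["Wx_b"], data["Wh_b"], data["b_b"]
            clf._Wd, clf._bd = data["Wd"], data["bd"]
            clf.baseline_scores_ = data["baseline"]
            clf.training_log_ = list(data["training_log"])
        return clf


def train_classifier(split: CorpusSplit, embedding: EmbeddingModel,
                     random_state: int | None = 0, **params) -> BiLSTMClassifier:
    """Fit a :class:`BiLSTMClassifier` on a corpus split."""
    X, y = split.arrays("train")
    clf = BiLSTMClassifier(
        embedding=embedding, n_categories=len(split.categories),
        random_state=random_state, **params)
    return clf.fit(X, y)


def evaluate_classifier(clf: BiLSTMClassifier, X, y,
                        categories=None) -> ClassifierMetrics:
    """Standard multi-class metrics on a held-out set.

    Accuracy is the argmax-correct fraction; precision/recall/F1 are
    micro-averaged over examples (macro also reported); AUROC is
    one-vs-rest per category, with the micro average computed over the
    flattened (example x category) score/indicator pairs, dropping
    categories whose indicator column is constant.
    """
    if len(np.asarray(y)) == 0:
        raise ValueError("test set is empty")
    y = np.asarray(y, dtype=np.int64)
    p = clf.predict_proba(X)
    yhat = np.argmax(p, axis=1)
    C = clf.n_categories_
    names = categories if categories is not None else [str(c) for c in range(C)]
    onehot = np.zeros_like(p)
    onehot[np.arange(len(y)), y] = 1.0
    per_cat = {}
    usable = []
    for c in range(C):
        col = onehot[:, c]
        if col.min() == col.max():
            per_cat[names[c]] = float("nan")
        else:
            per_cat[names[c]] = float(roc_auc_score(col, p[:, c]))
            usable.append(c)
    if usable:
        micro = float(roc_auc_score(onehot[:, usable].ravel(),
                                    p[:, usable].ravel()))
    else:
        micro = float("nan")
    confusion = np.zeros((C, C))
    for t, pr in zip(y, yhat):
        confusion[t, pr] += 1
    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(row_sums > 0, confusion / row_sums, 0.0)
    labels = list(range(C))
    return ClassifierMetrics(
        accuracy=float((yhat == y).mean()),
        precision_micro=float(precision_score(y, yhat, labels=labels,
                                              average="micro", zero_division=0)),
        recall_micro=float(recall_score(y, yhat, labels=labels,
                                        average="micro", zero_division=0)),
        f1_micro=float(f1_score(y, yhat, labels=labels, average="micro",
                                zero_division=0)),
        precision_macro=float(precision_score(y, yhat, labels=labels,
                                              average="macro", zero_division=0)),
        recall_macro=float(recall_score(y, yhat, labels=labels,
                                        average="macro", zero_division=0)),
        f1_macro=float(f1_score(y, yhat, labels=labels, average="macro",
                                zero_division=0)),
        per_category_auroc=per_cat,
        micro_average_auroc=micro,
        confusion=confusion,
    )
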