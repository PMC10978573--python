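"""Transfer learning: dense heads on top of the encoder.

A four-layer dense network is attached to mean-pooled encoder
representations: sigmoid output with binary cross-entropy for species
classification, linear output with mean squared error for thermostability
regression (targets min-max scaled to [0, 1] on the training split). Data are
split 8:1:1 with an optional sequence-identity restriction between train and
evaluation splits; regression experiments are repeated five times with
different training seeds and summarized as mean/SD of test Pearson r, with a
uniform-random baseline and a no-pretraining (random frozen encoder) control.
"""

from __future__ import annotations

import copy
import dataclasses
import logging

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.utils.validation import check_is_fitted

from . import nn
from .align import pairwise_identity
from .io import SequenceRecord
from .lm import MaskedLanguageModel, Vocabulary, _as_sequences

logger = logging.getLogger("vhhlm")


# ---------------------------------------------------------------------------
# small exact pieces
# ---------------------------------------------------------------------------

def pearson(x, y) -> float:
    """Product-moment correlation; requires equal lengths >= 3 and variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(scipy.stats.pearsonr(x, y)[0])


@dataclasses.dataclass
class TargetScaler:
    """Min-max map of targets (°C) to [0, 1], fitted on training data only."""

    observed_min: float = float("nan")
    observed_max: float = float("nan")

    def fit(self, values) -> "TargetScaler":
        v = np.asarray(values, dtype=float)
        self.observed_min = float(v.min())
        self.observed_max = float(v.max())
        if self.observed_max == self.observed_min:
            raise ValueError("target values have zero range")
        return self

    def transform(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.observed_min) \
            / (self.observed_max - self.observed_min)

    def inverse_transform(self, scaled) -> np.ndarray:
        return np.asarray(scaled, dtype=float) \
            * (self.observed_max - self.observed_min) + self.observed_min


@dataclasses.dataclass
class HeadConfig:
    """Four dense layers; the output activation determines the loss pairing."""

    hidden_dims: tuple[int, int, int] | None = None  # default from embedding dim
    output_activation: str = "linear"  # "sigmoid" | "linear"
    loss: str = "mse"  # "bce" | "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        pairs = {"sigmoid": "bce", "linear": "mse"}
        if self.output_activation not in pairs:
            raise ValueError("output_activation must be 'sigmoid' or 'linear'")
        if pairs[self.output_activation] != self.loss:
            raise ValueError("sigmoid pairs with bce, linear with mse")


@dataclasses.dataclass
class SplitSpec:
    """8:1:1 split with a train-vs-eval sequence-identity restriction."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    identity_threshold: float | None = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_with_identity_filter(records: list[SequenceRecord], spec: SplitSpec
                               ) -> tuple[list, list, list]:
    """Shuffled 8:1:1 split; val/test records within ``identity_threshold``
    global-alignment identity of any train record are dropped (with counts
    logged). Deterministic given ``spec.seed``."""
    if len(records) < 10:
        raise ValueError("need at least 10 records to split 8:1:1")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(records))
    n = len(records)
    n_train = round(spec.fractions[0] * n)
    n_val = round(spec.fractions[1] * n)
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train:n_train + n_val]]
    test = [records[i] for i in order[n_train + n_val:]]

    if spec.identity_threshold is not None:
        thr = spec.identity_threshold
        train_seqs = [r.sequence for r in train]

        def too_close(seq: str) -> bool:
            L = len(seq)
            for t in train_seqs:
                # identity <= min/max length: skip alignment when it can't reach thr
                if min(L, len(t)) / max(L, len(t)) < thr:
                    continue
                if seq == t or pairwise_identity(seq, t) >= thr:
                    return True
            return False

        kept_val = [r for r in val if not too_close(r.sequence)]
        kept_test = [r for r in test if not too_close(r.sequence)]
        n_dropped = (len(val) - len(kept_val)) + (len(test) - len(kept_test))
        if n_dropped:
            logger.info("identity filter dropped %d of %d eval records",
                        n_dropped, len(val) + len(test))
        val, test = kept_val, kept_test
        if not val or not test:
            raise ValueError(
                "identity filter emptied a split; lower the threshold or reseed")
    return train, val, test


def random_baseline(n_test: int, seed: int, targets=None) -> dict:
    """Uniform-[0,1] predictions; Pearson r reported when targets are given."""
    rng = np.random.default_rng(seed)
    scores = rng.random(n_test)
    out = {"scores": scores}
    if targets is not None:
        out["pearson_r"] = pearson(scores, targets)
    return out


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _pool_batches(seqs: list[str], vocab: Vocabulary, batch_size: int):
    for start in range(0, len(seqs), batch_size):
        chunk = seqs[start:start + batch_size]
        ids = [vocab.encode(s) for s in chunk]
        Lmax = max(len(b) for b in ids)
        toks = np.full((len(ids), Lmax), vocab.pad_id, dtype=np.int64)
        pad = np.zeros((len(ids), Lmax), dtype=bool)
        resmask = np.zeros((len(ids), Lmax), dtype=bool)
        for i, b in enumerate(ids):
            toks[i, :len(b)] = b
            pad[i, :len(b)] = True
            resmask[i, 1:len(b) - 1] = True
        yield start, toks, pad, resmask


class _FineTuneBase(BaseEstimator):
    """Shared machinery: pooled encoder + four-layer dense head."""

    _task: str = ""  # "classify" | "regress"

    def __init__(self, base_model: MaskedLanguageModel | None = None,
                 hidden_dims: tuple[int, int, int] | None = None,
                 learning_rate: float = 1e-3, n_epochs: int = 40,
                 batch_size: int = 32, freeze_encoder: bool = False,
                 pooling: str = "mean", encoder_params: dict | None = None,
                 head_warmup_epochs: int = 10, patience: int = 8,
                 random_state: int = 0):
        self.base_model = base_model
        self.hidden_dims = hidden_dims
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.freeze_encoder = freeze_encoder
        self.pooling = pooling
        self.encoder_params = encoder_params
        self.head_warmup_epochs = head_warmup_epochs
        self.patience = patience
        self.random_state = random_state

    # -- encoder handling ---------------------------------------------------

    def _init_encoder(self) -> None:
        if self.base_model is not None:
            src = self.base_model
            if not hasattr(src, "encoder_"):
                raise ValueError("base_model must be a fitted MaskedLanguageModel")
            self.vocab_ = src.vocab_
            self.encoder_ = copy.deepcopy(src.encoder_)
            self._dim = src.embedding_dim
        else:
            # no pre-training: a randomly initialized encoder of the same shape
            params = dict(n_layers=2, n_heads=4, embedding_dim=32,
                          feedforward_dim=128, max_positions=192)
            params.update(self.encoder_params or {})
            rng = np.random.default_rng(self.random_state)
            self.vocab_ = Vocabulary()
            self.encoder_ = nn.Encoder(rng, len(self.vocab_),
                                       params["embedding_dim"], params["n_layers"],
                                       params["n_heads"], params["feedforward_dim"],
                                       params["max_positions"])
            self._dim = params["embedding_dim"]

    def _init_head(self) -> None:
        d = self._dim
        dims = self.hidden_dims or (d, max(d // 2, 2), max(d // 4, 2))
        rng = np.random.default_rng(self.random_state + 1)
        # mean pooling shrinks feature scale by ~1/sqrt(L); normalize before
        # the head so its gradients start at a usable magnitude
        self.pool_norm_ = nn.LayerNorm(d)
        self.head_ = nn.DenseHead(rng, [d, *dims, 1])

    def _head_forward(self, pooled):
        return self.head_.forward(self.pool_norm_.forward(pooled))

    def _head_backward(self, dout):
        return self.pool_norm_.backward(self.head_.backward(dout))

    def _pool_forward(self, toks, pad, resmask, train):
        hidden = self.encoder_.forward(toks, pad, train=train)
        if self.pooling == "cls":
            pooled = hidden[:, 0, :]
        else:
            counts = resmask.sum(axis=1, keepdims=True)
            pooled = (hidden * resmask[:, :, None]).sum(axis=1) / counts
        return hidden, pooled

    def _pool_backward(self, dpooled, hidden, resmask):
        if self.pooling == "cls":
            dh = np.zeros_like(hidden)
            dh[:, 0, :] = dpooled
        else:
            counts = resmask.sum(axis=1)[:, None, None]
            dh = (resmask[:, :, None] * dpooled[:, None, :]) / counts
        self.encoder_.backward(dh.astype(nn.F32))

    # -- training -----------------------------------------------------------

    def _fit_core(self, X, y, X_val=None, y_val=None) -> "_FineTuneBase":
        seqs = _as_sequences(X)
        y = np.asarray(y, dtype=float)
        if len(seqs) != len(y):
            raise ValueError("X and y length mismatch")
        self._init_encoder()
        self._init_head()
        rng = np.random.default_rng(self.random_state)
        trainable = self.head_.params() + self.pool_norm_.params() \
            + ([] if self.freeze_encoder else self.encoder_.params())

        if not self.freeze_encoder and self.head_warmup_epochs > 0:
            # warm the head on frozen features first so early encoder updates
            # are not driven by a random head's gradients
            feats = self._features(seqs)
            warm_opt = nn.Adam(self.head_.params() + self.pool_norm_.params(),
                               lr=2e-3, warmup_steps=10)
            for _ in range(self.head_warmup_epochs):
                perm = rng.permutation(len(seqs))
                for start in range(0, len(perm), self.batch_size):
                    idx = perm[start:start + self.batch_size]
                    out = self._head_forward(feats[idx])[:, 0]
                    _, dout = self._loss_grad(out, y[idx])
                    warm_opt.zero_grad()
                    self._head_backward(dout[:, None].astype(nn.F32))
                    warm_opt.step()

        opt = nn.Adam(trainable, lr=self.learning_rate, warmup_steps=20)

        frozen_feats = None
        if self.freeze_encoder:
            frozen_feats = self._features(seqs)

        best_val = np.inf
        best_params = None
        stale = 0
        self.loss_trace_ = []
        for epoch in range(self.n_epochs):
            perm = rng.permutation(len(seqs))
            losses = []
            for start in range(0, len(perm), self.batch_size):
                idx = perm[start:start + self.batch_size]
                yb = y[idx]
                if frozen_feats is not None:
                    pooled = frozen_feats[idx]
                    hidden = resmask = None
                else:
                    chunk = [seqs[i] for i in idx]
                    _, toks, pad, resmask = next(_pool_batches(
                        chunk, self.vocab_, len(chunk)))
                    hidden, pooled = self._pool_forward(toks, pad, resmask, True)
                out = self._head_forward(pooled.astype(nn.F32))[:, 0]
                loss, dout = self._loss_grad(out, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(f"fine-tuning diverged at epoch {epoch}")
                opt.zero_grad()
                dpooled = self._head_backward(dout[:, None].astype(nn.F32))
                if frozen_feats is None:
                    self._pool_backward(dpooled, hidden, resmask)
                opt.step()
                losses.append(loss)
            self.loss_trace_.append(float(np.mean(losses)))
            if X_val is not None:
                vout = self._raw_predict(X_val)
                vloss, _ = self._loss_grad(vout, np.asarray(y_val, dtype=float))
                if vloss < best_val - 1e-6:
                    best_val = vloss
                    best_params = [p.value.copy() for p in trainable]
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_params is not None:
            for p, v in zip(trainable, best_params):
                p.value = v
        return self

    def _features(self, seqs: list[str]) -> np.ndarray:
        feats = np.empty((len(seqs), self._dim), dtype=nn.F32)
        for start, toks, pad, resmask in _pool_batches(seqs, self.vocab_,
                                                       self.batch_size):
            _, pooled = self._pool_forward(toks, pad, resmask, False)
            feats[start:start + toks.shape[0]] = pooled
        return feats

    def _raw_predict(self, X) -> np.ndarray:
        check_is_fitted(self, "head_")
        seqs = _as_sequences(X)
        return self._head_forward(self._features(seqs))[:, 0].astype(float)


class SequenceClassifier(_FineTuneBase, ClassifierMixin):
    """Binary classifier: pooled encoder + four-layer head, sigmoid/BCE."""

    _task = "classify"

    def _loss_grad(self, logits, y):
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-7
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        return loss, (p - y) / len(y)

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly two classes")
        ybin = (y == self.classes_[1]).astype(float)
        return self._fit_core(X, ybin)

    def decision_function(self, X) -> np.ndarray:
        return self._raw_predict(X)

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self._raw_predict(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self._raw_predict(X) > 0).astype(int)]


class SequenceRegressor(_FineTuneBase, RegressorMixin):
    """Regressor: pooled encoder + four-layer head, linear/MSE on scaled targets."""

    _task = "regress"

    def _loss_grad(self, out, y):
        diff = out - y
        return float(np.mean(diff ** 2)), 2.0 * diff / len(y)

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on scaled targets; a validation set enables early stopping
        (best-epoch weights restored)."""
        y = np.asarray(y, dtype=float)
        if np.std(y) == 0:
            raise ValueError("target values have zero variance")
        self.scaler_ = TargetScaler().fit(y)
        yv = self.scaler_.transform(y_val) if y_val is not None else None
        return self._fit_core(X, self.scaler_.transform(y), X_val=X_val,
                              y_val=yv)

    def predict(self, X) -> np.ndarray:
        return self.scaler_.inverse_transform(self._raw_predict(X))


# ---------------------------------------------------------------------------
# experiment protocols
# ---------------------------------------------------------------------------

def finetune_classifier(model: MaskedLanguageModel | None,
                        records: list[SequenceRecord], labels: list,
                        spec: SplitSpec, **estimator_kwargs) -> dict:
    """Split, fit a species classifier, report test ROC-AUC and PR-AUC."""
    by_id = dict(zip([r.id for r in records], labels))
    train, val, test = split_with_identity_filter(records, spec)
    for part, name in ((train, "train"), (val, "val"), (test, "test")):
        if len({by_id[r.id] for r in part}) < 2:
            raise ValueError(f"{name} split contains a single class")
    clf = SequenceClassifier(base_model=model, random_state=spec.seed,
                             **estimator_kwargs)
    y_val = np.asarray([by_id[r.id] for r in val])
    y_tr = np.asarray([by_id[r.id] for r in train])
    clf.classes_ = np.unique(np.concatenate([y_tr, y_val]))
    clf._fit_core(train, (y_tr == clf.classes_[1]).astype(float),
                  X_val=val, y_val=(y_val == clf.classes_[1]).astype(float))
    y_test = np.asarray([by_id[r.id] for r in test])
    scores = clf.decision_function(test)
    ybin = (y_test == clf.classes_[1]).astype(int)
    return {"roc_auc": float(roc_auc_score(ybin, scores)),
            "pr_auc": float(average_precision_score(ybin, scores)),
            "n_train": len(train), "n_val": len(val), "n_test": len(test)}


def finetune_regressor(model: MaskedLanguageModel | None,
                       records: list[SequenceRecord], spec: SplitSpec,
                       repeats: int = 5, **estimator_kwargs) -> dict:
    """Five-repeat fine-tuning on a fixed split; mean/SD of test Pearson r.

    Repeats re-seed training (initialisation and batching) on the same split.
    Records must carry ``measurement`` values.
    """
    labeled = [r for r in records if r.measurement is not None]
    if len(labeled) < 50:
        raise ValueError("need at least 50 labeled records")
    train, val, test = split_with_identity_filter(labeled, spec)
    y_train = [r.measurement for r in train]
    y_val = np.array([r.measurement for r in val])
    y_test = np.array([r.measurement for r in test])
    kwargs = dict(estimator_kwargs)
    kwargs.setdefault("learning_rate", 5e-4)  # whole-encoder fine-tuning
    rs = []
    for rep in range(repeats):
        reg = SequenceRegressor(base_model=model,
                                random_state=spec.seed + 1000 * (rep + 1),
                                **kwargs)
        reg.fit(train, y_train, X_val=val, y_val=y_val)
        preds = reg.predict(test)
        if np.std(preds) == 0:
            # a collapsed head predicts a constant; it carries no correlation
            logger.warning("repeat %d produced constant predictions; r := 0", rep)
            rs.append(0.0)
        else:
            rs.append(pearson(preds, y_test))
    return {"per_repeat_r": rs, "mean_r": float(np.mean(rs)),
            "sd_r": float(np.std(rs, ddof=1)) if repeats > 1 else 0.0,
            "n_train": len(train), "n_val": len(val), "n_test": len(test)}
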