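"""Residue-level masked language model.

Each residue is a token and each variable-domain sequence a sentence; a
bidirectional encoder is trained to reconstruct masked residues from both-side
context. :class:`MaskedLanguageModel` is a scikit-learn style estimator:
``fit`` on an unlabeled corpus of sequences, then query per-position residue
distributions with :meth:`predict_position` / :meth:`predict_all_positions`.

Presets mirror published antibody-LM scales: ``tiny`` (2 layers, embedding 32)
for tests and desk experiments, ``small`` (~15M parameters, embedding 320) and
``big`` (~86M, embedding 768) for users with real compute.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import nn
from .io import AMINO_ACIDS, SequenceRecord

logger = logging.getLogger("vhhlm")

SPECIALS = ("[MASK]", "[PAD]", "[CLS]", "[SEP]", "[UNK]")


class Vocabulary:
    """20 canonical residues (alphabetical) followed by the five special tokens."""

    def __init__(self) -> None:
        self.tokens: list[str] = list(AMINO_ACIDS) + list(SPECIALS)
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        self.mask_id = self.token_to_id["[MASK]"]
        self.pad_id = self.token_to_id["[PAD]"]
        self.cls_id = self.token_to_id["[CLS]"]
        self.sep_id = self.token_to_id["[SEP]"]
        self.unk_id = self.token_to_id["[UNK]"]

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, seq: str) -> list[int]:
        if not seq:
            raise ValueError("cannot tokenize an empty sequence")
        ids = [self.cls_id]
        for ch in seq.upper():
            tid = self.token_to_id.get(ch, self.unk_id)
            if tid == self.unk_id:
                logger.warning("non-canonical residue %r mapped to [UNK]", ch)
            ids.append(tid)
        ids.append(self.sep_id)
        return ids

    def decode(self, ids: list[int]) -> str:
        return "".join(self.tokens[i] for i in ids
                       if self.tokens[i] not in SPECIALS)


def tokenize(seq: str, vocab: Vocabulary) -> list[int]:
    """CLS + residue tokens + SEP."""
    return vocab.encode(seq)


def detokenize(ids: list[int], vocab: Vocabulary) -> str:
    return vocab.decode(ids)


@dataclasses.dataclass
class MaskPolicy:
    """BERT-standard corruption: of the selected positions, ``replace_with_mask``
    become [MASK], ``replace_with_random`` a random residue, the rest stay."""

    mask_fraction: float = 0.15
    replace_with_mask: float = 0.8
    replace_with_random: float = 0.1
    keep_original: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must be in [0, 1]")
        total = self.replace_with_mask + self.replace_with_random + self.keep_original
        if abs(total - 1.0) > 1e-9:
            raise ValueError("corruption fractions must sum to 1")


def apply_mask(batch: list[list[int]], policy: MaskPolicy, vocab: Vocabulary,
               rng: np.random.Generator | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corrupt a batch of token-id lists for MLM training.

    Returns (tokens (B, Lmax) with PAD, labels (B, Lmax) with -1 at unlabeled
    positions, pad_mask (B, Lmax) bool). Per sequence,
    ceil(mask_fraction * n_residues) residue positions (never CLS/SEP/PAD, at
    least one) are selected without replacement.
    """
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    B = len(batch)
    Lmax = max(len(ids) for ids in batch)
    tokens = np.full((B, Lmax), vocab.pad_id, dtype=np.int64)
    labels = np.full((B, Lmax), -1, dtype=np.int64)
    pad_mask = np.zeros((B, Lmax), dtype=bool)
    for i, ids in enumerate(batch):
        L = len(ids)
        tokens[i, :L] = ids
        pad_mask[i, :L] = True
        n_res = L - 2
        if n_res <= 0:
            continue
        k = max(1, math.ceil(policy.mask_fraction * n_res))
        chosen = rng.choice(n_res, size=min(k, n_res), replace=False) + 1
        for j in chosen:
            labels[i, j] = tokens[i, j]
            u = rng.random()
            if u < policy.replace_with_mask:
                tokens[i, j] = vocab.mask_id
            elif u < policy.replace_with_mask + policy.replace_with_random:
                tokens[i, j] = rng.integers(0, 20)
            # else: keep original
    return tokens, labels, pad_mask


#: architecture presets: (n_layers, n_heads, embedding_dim, feedforward_dim)
PRESETS: dict[str, tuple[int, int, int, int]] = {
    "tiny": (2, 4, 32, 128),
    "small": (12, 8, 320, 1280),
    "big": (12, 12, 768, 3072),
}


def _as_sequences(X) -> list[str]:
    out = []
    for x in X:
        out.append(x.sequence if isinstance(x, SequenceRecord) else str(x))
    return out


class MaskedLanguageModel(BaseEstimator):
    """BERT-style masked language model over amino-acid sequences.

    Parameters follow scikit-learn conventions; ``fit(X)`` takes a list of
    sequences (strings or records). After fitting, ``predict_position`` and
    ``predict_all_positions`` return residue distributions at masked
    positions, and ``encode`` exposes pooled hidden states for transfer
    learning.

    Use :meth:`from_preset` for the named architecture scales.
    """

    def __init__(self, n_layers: int = 2, n_heads: int = 4, embedding_dim: int = 32,
                 feedforward_dim: int = 128, max_positions: int = 192,
                 dropout: float = 0.0, mask_fraction: float = 0.15,
                 replace_with_mask: float = 0.8, replace_with_random: float = 0.1,
                 keep_original: float = 0.1, learning_rate: float = 1e-3,
                 batch_size: int = 64, n_epochs: int = 3, warmup_steps: int = 100,
                 validation_fraction: float = 0.01, random_state: int = 0):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.embedding_dim = embedding_dim
        self.feedforward_dim = feedforward_dim
        self.max_positions = max_positions
        self.dropout = dropout
        self.mask_fraction = mask_fraction
        self.replace_with_mask = replace_with_mask
        self.replace_with_random = replace_with_random
        self.keep_original = keep_original
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.warmup_steps = warmup_steps
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "MaskedLanguageModel":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        n_layers, n_heads, d, d_ff = PRESETS[preset]
        kw = dict(n_layers=n_layers, n_heads=n_heads, embedding_dim=d,
                  feedforward_dim=d_ff)
        kw.update(overrides)
        return cls(**kw)

    # -- construction -------------------------------------------------------

    def _build(self) -> None:
        if self.max_positions < 160:
            raise ValueError("max_positions must be >= 160")
        if self.embedding_dim % self.n_heads:
            raise ValueError("embedding_dim must be divisible by n_heads")
        rng = np.random.default_rng(self.random_state)
        self.vocab_ = Vocabulary()
        self.encoder_ = nn.Encoder(rng, len(self.vocab_), self.embedding_dim,
                                   self.n_layers, self.n_heads,
                                   self.feedforward_dim, self.max_positions,
                                   self.dropout)
        self.head_ = nn.MlmHead(rng, self.embedding_dim, len(self.vocab_))
        self.n_parameters_ = nn.n_parameters([self.encoder_, self.head_])

    def _policy(self) -> MaskPolicy:
        return MaskPolicy(self.mask_fraction, self.replace_with_mask,
                          self.replace_with_random, self.keep_original,
                          seed=self.random_state)

    def _params(self):
        return self.encoder_.params() + self.head_.params()

    # -- training -----------------------------------------------------------

    def fit(self, X, y=None) -> "MaskedLanguageModel":
        seqs = _as_sequences(X)
        if not seqs:
            raise ValueError("corpus is empty")
        self._build()
        policy = self._policy()
        rng = np.random.default_rng(self.random_state)

        n_val = int(round(self.validation_fraction * len(seqs)))
        n_val = min(max(n_val, 1 if self.validation_fraction > 0 and len(seqs) > 1 else 0),
                    len(seqs) - 1)
        order = rng.permutation(len(seqs))
        train_seqs = [seqs[i] for i in order[n_val:]]
        val_seqs = [seqs[i] for i in order[:n_val]]
        tokens_train = [self.vocab_.encode(s) for s in train_seqs]
        tokens_val = [self.vocab_.encode(s) for s in val_seqs]

        opt = nn.Adam(self._params(), lr=self.learning_rate,
                      warmup_steps=self.warmup_steps)
        self.loss_trace_ = []
        for epoch in range(self.n_epochs):
            perm = rng.permutation(len(tokens_train))
            losses = []
            for start in range(0, len(perm), self.batch_size):
                idx = perm[start:start + self.batch_size]
                batch = [tokens_train[i] for i in idx]
                toks, labels, pad = apply_mask(batch, policy, self.vocab_, rng)
                hidden = self.encoder_.forward(toks, pad, train=True)
                logits = self.head_.forward(hidden)
                loss, dlogits = nn.softmax_xent(
                    logits.reshape(-1, len(self.vocab_)), labels.reshape(-1))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss}")
                opt.zero_grad()
                self.encoder_.backward(self.head_.backward(
                    dlogits.reshape(logits.shape)))
                opt.step()
                losses.append(loss)
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if tokens_val:
                entry["val_loss"] = self._eval_loss(tokens_val, policy)
            self.loss_trace_.append(entry)
            logger.info("epoch %d: %s", epoch, entry)
        self.n_sequences_ = len(seqs)
        return self

    def _eval_loss(self, tokens: list[list[int]], policy: MaskPolicy) -> float:
        rng = np.random.default_rng(policy.seed + 1)  # fixed val corruption
        losses, weights = [], []
        for start in range(0, len(tokens), self.batch_size):
            batch = tokens[start:start + self.batch_size]
            toks, labels, pad = apply_mask(batch, policy, self.vocab_, rng)
            logits = self.head_.forward(self.encoder_.forward(toks, pad))
            loss, _ = nn.softmax_xent(logits.reshape(-1, len(self.vocab_)),
                                      labels.reshape(-1))
            losses.append(loss)
            weights.append(int((labels >= 0).sum()))
        return float(np.average(losses, weights=weights))

    # -- inference ----------------------------------------------------------

    def _masked_rows(self, seq: str, positions: list[int]) -> np.ndarray:
        """Raw head logits (n_positions, vocab) with each listed position masked."""
        check_is_fitted(self, "encoder_")
        base = self.vocab_.encode(seq)
        rows = []
        for p in positions:
            if not 0 <= p < len(seq):
                raise ValueError(f"position {p} out of range for length {len(seq)}")
            ids = list(base)
            ids[p + 1] = self.vocab_.mask_id
            rows.append(ids)
        toks = np.array(rows, dtype=np.int64)
        pad = np.ones_like(toks, dtype=bool)
        out = np.empty((len(positions), len(self.vocab_)), dtype=np.float64)
        chunk = 128
        for s in range(0, len(rows), chunk):
            logits = self.head_.forward(
                self.encoder_.forward(toks[s:s + chunk], pad[s:s + chunk]))
            for k, p in enumerate(positions[s:s + chunk]):
                out[s + k] = logits[k, p + 1]
        return out

    def position_logits(self, seq: str, positions: list[int] | None = None
                        ) -> np.ndarray:
        """Final-layer logits of the MLM head at masked positions.

        Rows are (vocab,) raw logits; one forward pass per sequence, batched
        over positions. Default: every position.
        """
        if positions is None:
            positions = list(range(len(seq)))
        return self._masked_rows(seq, positions)

    def predict_position(self, seq: str, position: int) -> np.ndarray:
        """Residue distribution at ``position`` with that position masked.

        Softmax over the 20 residue tokens only (special-token mass excluded
        and renormalized); sums to 1.
        """
        logits = self._masked_rows(seq, [position])[0, :20]
        z = logits - logits.max()
        p = np.exp(z)
        return p / p.sum()

    def predict_all_positions(self, seq: str) -> np.ndarray:
        """(L, 20) matrix of per-position residue distributions, one masked
        forward per position, batched into a single encoder call."""
        logits = self._masked_rows(seq, list(range(len(seq))))[:, :20]
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def encode(self, X, pooling: str = "mean") -> np.ndarray:
        """Pooled final hidden states, one row per sequence.

        ``mean`` averages residue positions (CLS/SEP excluded); ``cls`` takes
        the CLS vector.
        """
        check_is_fitted(self, "encoder_")
        seqs = _as_sequences(X)
        out = np.empty((len(seqs), self.embedding_dim))
        for start in range(0, len(seqs), self.batch_size):
            chunk = seqs[start:start + self.batch_size]
            batch = [self.vocab_.encode(s) for s in chunk]
            Lmax = max(len(b) for b in batch)
            toks = np.full((len(batch), Lmax), self.vocab_.pad_id, dtype=np.int64)
            pad = np.zeros((len(batch), Lmax), dtype=bool)
            for i, b in enumerate(batch):
                toks[i, :len(b)] = b
                pad[i, :len(b)] = True
            hidden = self.encoder_.forward(toks, pad)
            for i, b in enumerate(batch):
                if pooling == "cls":
                    out[start + i] = hidden[i, 0]
                else:
                    out[start + i] = hidden[i, 1:len(b) - 1].mean(axis=0)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Checkpoint layout: config.json, vocab.json, weights.npz."""
        check_is_fitted(self, "encoder_")
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(self.get_params(), indent=2))
        (d / "vocab.json").write_text(json.dumps(self.vocab_.tokens))
        arrays = {f"p{i}": p.value for i, p in enumerate(self._params())}
        np.savez(d / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "MaskedLanguageModel":
        d = Path(directory)
        params = json.loads((d / "config.json").read_text())
        model = cls(**params)
        model._build()
        tokens = json.loads((d / "vocab.json").read_text())
        if tokens != model.vocab_.tokens:
            raise ValueError("checkpoint vocabulary does not match")
        with np.load(d / "weights.npz") as data:
            for i, p in enumerate(model._params()):
                p.value = data[f"p{i}"].astype(nn.F32)
        model.loss_trace_ = []
        return model


def train_mlm(corpus, preset: str = "tiny", **kwargs) -> MaskedLanguageModel:
    """Functional wrapper: fit a preset MLM on a corpus of sequences."""
    return MaskedLanguageModel.from_preset(preset, **kwargs).fit(corpus)
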