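"""Minimal transformer encoder in numpy with hand-written backpropagation.

Residue-level BERT-style encoder: learned token + position embeddings,
pre-LayerNorm multi-head self-attention blocks, GELU feed-forward, and a
masked-language-model head. Written directly in numpy so the package is
self-contained on a CPU-only scientific Python stack; at the "tiny" scale the
tests and experiments use, numpy matmuls are entirely adequate.

All arrays are float32. Every module caches what its backward pass needs;
``backward`` must be called in reverse order of ``forward`` (the training
loops here do exactly one forward/backward per step, so caches are simple
attributes rather than tapes).
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


def _init_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, std, size=shape).astype(F32)


def gelu(x: np.ndarray) -> np.ndarray:
    # tanh approximation (BERT convention); x*x*x avoids numpy's slow pow
    c = np.float32(np.sqrt(2.0 / np.pi))
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * (x * x * x))))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    c = np.float32(np.sqrt(2.0 / np.pi))
    u = c * (x + 0.044715 * (x * x * x))
    t = np.tanh(u)
    du = c * (1.0 + (3 * 0.044715) * (x * x))
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du


class Linear:
    def __init__(self, rng, d_in: int, d_out: int, init_std: float | None = None):
        self.W = Param(_init_normal(rng, (d_in, d_out),
                                    0.02 if init_std is None else init_std))
        self.b = Param(np.zeros(d_out, dtype=F32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Param(np.ones(d, dtype=F32))
        self.b = Param(np.zeros(d, dtype=F32))
        self.eps = F32(eps)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = xc * self._inv
        return self.g.value * self._xhat + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        d = xhat.shape[-1]
        self.g.grad += (dy * xhat).reshape(-1, d).sum(axis=0)
        self.b.grad += dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.g.value
        return inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                      - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))

    def params(self):
        return [self.g, self.b]


class MultiHeadAttention:
    def __init__(self, rng, d: int, n_heads: int):
        if d % n_heads:
            raise ValueError("embedding_dim must be divisible by n_heads")
        self.d, self.h = d, n_heads
        self.dh = d // n_heads
        self.qkv = Linear(rng, d, 3 * d)
        self.proj = Linear(rng, d, d)

    def _split(self, x):  # (B,L,d) -> (B,h,L,dh)
        B, L, _ = x.shape
        return x.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
        """pad_mask: (B, L) boolean, True at valid tokens."""
        B, L, d = x.shape
        qkv = self.qkv.forward(x)
        q, k, v = np.split(qkv, 3, axis=-1)
        q, k, v = self._split(q), self._split(k), self._split(v)
        scores = (q @ k.transpose(0, 1, 3, 2)) / np.float32(np.sqrt(self.dh))
        neg = np.float32(-1e9)
        scores = np.where(pad_mask[:, None, None, :], scores, neg)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        a = e / e.sum(axis=-1, keepdims=True)
        self._a, self._q, self._k, self._v = a, q, k, v
        out = a @ v  # (B,h,L,dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.proj.forward(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, d = dy.shape
        dout = self.proj.backward(dy)
        dout = dout.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)
        a, q, k, v = self._a, self._q, self._k, self._v
        da = dout @ v.transpose(0, 1, 3, 2)
        dv = a.transpose(0, 1, 3, 2) @ dout
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        ds /= np.float32(np.sqrt(self.dh))
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        def merge(t):  # (B,h,L,dh) -> (B,L,d)
            return t.transpose(0, 2, 1, 3).reshape(B, L, d)
        dqkv = np.concatenate([merge(dq), merge(dk), merge(dv)], axis=-1)
        return self.qkv.backward(dqkv)

    def params(self):
        return self.qkv.params() + self.proj.params()


class FeedForward:
    def __init__(self, rng, d: int, d_ff: int):
        self.fc1 = Linear(rng, d, d_ff)
        self.fc2 = Linear(rng, d_ff, d)

    def forward(self, x):
        self._h = self.fc1.forward(x)
        return self.fc2.forward(gelu(self._h))

    def backward(self, dy):
        dh = self.fc2.backward(dy) * gelu_grad(self._h)
        return self.fc1.backward(dh)

    def params(self):
        return self.fc1.params() + self.fc2.params()


class Dropout:
    """Inverted dropout; identity when p == 0 or in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train: bool):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / F32(1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Block:
    """Pre-LayerNorm transformer block: x + Attn(LN(x)), then x + FF(LN(x))."""

    def __init__(self, rng, d: int, n_heads: int, d_ff: int, dropout: float = 0.0):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadAttention(rng, d, n_heads)
        self.ln2 = LayerNorm(d)
        self.ff = FeedForward(rng, d, d_ff)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x, pad_mask, train: bool = False):
        x = x + self.drop1.forward(self.attn.forward(self.ln1.forward(x), pad_mask), train)
        return x + self.drop2.forward(self.ff.forward(self.ln2.forward(x)), train)

    def backward(self, dy):
        dx = dy + self.ln2.backward(self.ff.backward(self.drop2.backward(dy)))
        return dx + self.ln1.backward(self.attn.backward(self.drop1.backward(dx)))

    def params(self):
        return self.ln1.params() + self.attn.params() + self.ln2.params() + self.ff.params()


class Encoder:
    def __init__(self, rng, vocab_size: int, d: int, n_layers: int, n_heads: int,
                 d_ff: int, max_positions: int, dropout: float = 0.0):
        self.tok = Param(_init_normal(rng, (vocab_size, d)))
        self.pos = Param(_init_normal(rng, (max_positions, d)))
        self.blocks = [Block(rng, d, n_heads, d_ff, dropout) for _ in range(n_layers)]
        self.ln_f = LayerNorm(d)
        self.max_positions = max_positions

    def forward(self, tokens: np.ndarray, pad_mask: np.ndarray,
                train: bool = False) -> np.ndarray:
        B, L = tokens.shape
        if L > self.max_positions:
            raise ValueError(f"sequence length {L} exceeds max_positions {self.max_positions}")
        self._tokens = tokens
        x = self.tok.value[tokens] + self.pos.value[:L]
        for blk in self.blocks:
            x = blk.forward(x, pad_mask, train)
        return self.ln_f.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dx = self.ln_f.backward(dy)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        np.add.at(self.tok.grad, self._tokens, dx)
        self.pos.grad[:dx.shape[1]] += dx.sum(axis=0)

    def params(self):
        ps = [self.tok, self.pos]
        for blk in self.blocks:
            ps += blk.params()
        return ps + self.ln_f.params()


class MlmHead:
    """BERT-style prediction head: dense + GELU + LayerNorm + vocab projection."""

    def __init__(self, rng, d: int, vocab_size: int):
        self.dense = Linear(rng, d, d)
        self.ln = LayerNorm(d)
        self.out = Linear(rng, d, vocab_size)

    def forward(self, h):
        self._z = self.dense.forward(h)
        return self.out.forward(self.ln.forward(gelu(self._z)))

    def backward(self, dlogits):
        dg = self.ln.backward(self.out.backward(dlogits))
        return self.dense.backward(dg * gelu_grad(self._z))

    def params(self):
        return self.dense.params() + self.ln.params() + self.out.params()


class DenseHead:
    """Stack of dense layers with ReLU between them; final layer linear.

    Used as the four-layer fine-tuning head; the output activation
    (sigmoid/identity) is applied by the loss, not here.
    """

    def __init__(self, rng, dims: list[int]):
        # He initialization: keeps ReLU activations alive on unit-scale inputs
        self.layers = [Linear(rng, a, b, init_std=float(np.sqrt(2.0 / a)))
                       for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, x):
        self._pre = []
        for i, lin in enumerate(self.layers):
            x = lin.forward(x)
            if i < len(self.layers) - 1:
                self._pre.append(x)
                x = np.maximum(x, 0)
        return x

    def backward(self, dy):
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                dy = dy * (self._pre[i] > 0)
            dy = self.layers[i].backward(dy)
        return dy

    def params(self):
        return [p for lin in self.layers for p in lin.params()]


def softmax_xent(logits: np.ndarray, labels: np.ndarray
                 ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over positions where labels >= 0.

    logits: (N, V); labels: (N,) with -1 meaning "ignore".
    Returns (loss, dlogits) with dlogits already divided by the count.
    """
    keep = labels >= 0
    n = int(keep.sum())
    if n == 0:
        return 0.0, np.zeros_like(logits)
    z = logits - logits.max(axis=-1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsum
    loss = -logp[keep, labels[keep]].sum() / n
    dl = np.exp(logp)
    dl[keep, labels[keep]] -= 1.0
    dl[~keep] = 0.0
    return float(loss), (dl / n).astype(F32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, warmup_steps: int = 100):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.warmup = max(warmup_steps, 1)
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        lr = self.lr * min(1.0, self.t / self.warmup)
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= (lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(F32)


def n_parameters(modules) -> int:
    return sum(int(np.prod(p.value.shape)) for m in modules for p in m.params())
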