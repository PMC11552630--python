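"""A compact Vision Transformer in pure NumPy.

Forward pass, manual backpropagation and Adam live here so the patch
classifier trains deterministically on a CPU from a single integer
seed.  The architecture is the standard pre-norm ViT: linear patch
embedding + learned positional embeddings, ``depth`` blocks of
multi-head self-attention and a GELU MLP with residual connections,
a final layer norm, mean pooling over tokens, and a two-logit head.

Everything is float64; gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

_EPS = 1e-6  # layer-norm epsilon
_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ViTSpec:
    """Architecture hyperparameters (patchify geometry + width/depth)."""

    image_size: int = 128
    patch_size: int = 8
    in_channels: int = 3
    width: int = 128
    depth: int = 4
    n_heads: int = 4
    mlp_ratio: int = 4
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.width % self.n_heads:
            raise ValueError("width must be divisible by n_heads")

    @property
    def n_tokens(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def token_dim(self) -> int:
        return self.patch_size * self.patch_size * self.in_channels


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, H, W, C) -> (B, T, patch_size*patch_size*C) token array."""
    b, h, w, c = images.shape
    p = patch_size
    x = images.reshape(b, h // p, p, w // p, p, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, (h // p) * (w // p), p * p * c)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return cdf + x * pdf


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    d = xhat.shape[-1]
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


def _linear_fwd(x, w, b):
    return x @ w + b, x


def _linear_bwd(dy, x, w):
    axes = tuple(range(dy.ndim - 1))
    dw = np.tensordot(x, dy, axes=(axes, axes))
    db = dy.sum(axis=axes)
    dx = dy @ w.T
    return dx, dw, db


class TinyViT:
    """Trainable NumPy ViT with a two-class softmax head."""

    def __init__(self, spec: ViTSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d, t = spec.width, spec.n_tokens
        std = 0.02

        def w(*shape):
            return rng.normal(0.0, std, size=shape)

        p: dict[str, np.ndarray] = {
            "embed_W": w(spec.token_dim, d), "embed_b": np.zeros(d),
            "pos": w(t, d),
            "lnf_g": np.ones(d), "lnf_b": np.zeros(d),
            "head_W": w(d, spec.n_classes), "head_b": np.zeros(spec.n_classes),
        }
        for l in range(spec.depth):
            p[f"b{l}_ln1_g"] = np.ones(d)
            p[f"b{l}_ln1_b"] = np.zeros(d)
            p[f"b{l}_qkv_W"] = w(d, 3 * d)
            p[f"b{l}_qkv_b"] = np.zeros(3 * d)
            p[f"b{l}_proj_W"] = w(d, d)
            p[f"b{l}_proj_b"] = np.zeros(d)
            p[f"b{l}_ln2_g"] = np.ones(d)
            p[f"b{l}_ln2_b"] = np.zeros(d)
            p[f"b{l}_fc1_W"] = w(d, spec.mlp_ratio * d)
            p[f"b{l}_fc1_b"] = np.zeros(spec.mlp_ratio * d)
            p[f"b{l}_fc2_W"] = w(spec.mlp_ratio * d, d)
            p[f"b{l}_fc2_b"] = np.zeros(d)
        self.params = p

    # ---------------- forward ----------------

    def _attn_fwd(self, h, l):
        p, s = self.params, self.spec
        nh, dh = s.n_heads, s.width // s.n_heads
        b, t, d = h.shape
        qkv, _ = _linear_fwd(h, p[f"b{l}_qkv_W"], p[f"b{l}_qkv_b"])
        qkv = qkv.reshape(b, t, 3, nh, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (b, nh, t, dh)
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh)
        att = _softmax(scores)
        o = att @ v                               # (b, nh, t, dh)
        o_merged = o.transpose(0, 2, 1, 3).reshape(b, t, d)
        out, _ = _linear_fwd(o_merged, p[f"b{l}_proj_W"], p[f"b{l}_proj_b"])
        return out, (h, q, k, v, att, o_merged)

    def _attn_bwd(self, dout, cache, l, grads):
        p, s = self.params, self.spec
        nh, dh = s.n_heads, s.width // s.n_heads
        h, q, k, v, att, o_merged = cache
        b, t, d = h.shape
        do_merged, dw, dbias = _linear_bwd(dout, o_merged, p[f"b{l}_proj_W"])
        grads[f"b{l}_proj_W"] += dw
        grads[f"b{l}_proj_b"] += dbias
        do = do_merged.reshape(b, t, nh, dh).transpose(0, 2, 1, 3)
        datt = do @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ do
        dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dscores /= math.sqrt(dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dqkv = np.stack([dq, dk, dv])             # (3, b, nh, t, dh)
        dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(b, t, 3 * d)
        dh_, dw, dbias = _linear_bwd(dqkv, h, p[f"b{l}_qkv_W"])
        grads[f"b{l}_qkv_W"] += dw
        grads[f"b{l}_qkv_b"] += dbias
        return dh_

    def forward(self, tokens: np.ndarray, need_cache: bool = False):
        """tokens: (B, T, token_dim) -> logits (B, n_classes)."""
        p, s = self.params, self.spec
        caches: list = []
        x = tokens @ p["embed_W"] + p["embed_b"] + p["pos"]
        for l in range(s.depth):
            h, ln1c = _layernorm_fwd(x, p[f"b{l}_ln1_g"], p[f"b{l}_ln1_b"])
            a, attc = self._attn_fwd(h, l)
            x = x + a
            h2, ln2c = _layernorm_fwd(x, p[f"b{l}_ln2_g"], p[f"b{l}_ln2_b"])
            z1, _ = _linear_fwd(h2, p[f"b{l}_fc1_W"], p[f"b{l}_fc1_b"])
            g1 = _gelu(z1)
            m, _ = _linear_fwd(g1, p[f"b{l}_fc2_W"], p[f"b{l}_fc2_b"])
            x = x + m
            caches.append((ln1c, attc, ln2c, h2, z1, g1))
        y, lnfc = _layernorm_fwd(x, p["lnf_g"], p["lnf_b"])
        pooled = y.mean(axis=1)
        logits = pooled @ p["head_W"] + p["head_b"]
        if need_cache:
            return logits, (tokens, caches, lnfc, y, pooled)
        return logits

    # ---------------- loss & gradients ----------------

    def loss_and_grads(self, tokens: np.ndarray, labels: np.ndarray):
        """Mean cross-entropy and gradients w.r.t. every parameter."""
        p, s = self.params, self.spec
        logits, (tokens, caches, lnfc, y, pooled) = self.forward(tokens, need_cache=True)
        b, t = tokens.shape[0], s.n_tokens
        probs = _softmax(logits)
        loss = -np.log(probs[np.arange(b), labels] + 1e-300).mean()

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = probs.copy()
        dlogits[np.arange(b), labels] -= 1.0
        dlogits /= b

        dpooled, dw, dbias = _linear_bwd(dlogits, pooled, p["head_W"])
        grads["head_W"] += dw
        grads["head_b"] += dbias
        dy = np.repeat(dpooled[:, None, :], t, axis=1) / t
        dx, dg, db = _layernorm_bwd(dy, lnfc)
        grads["lnf_g"] += dg
        grads["lnf_b"] += db

        for l in reversed(range(s.depth)):
            ln1c, attc, ln2c, h2, z1, g1 = caches[l]
            # MLP branch
            dg1, dw, dbias = _linear_bwd(dx, g1, p[f"b{l}_fc2_W"])
            grads[f"b{l}_fc2_W"] += dw
            grads[f"b{l}_fc2_b"] += dbias
            dz1 = dg1 * _gelu_grad(z1)
            dh2, dw, dbias = _linear_bwd(dz1, h2, p[f"b{l}_fc1_W"])
            grads[f"b{l}_fc1_W"] += dw
            grads[f"b{l}_fc1_b"] += dbias
            dres, dg, db = _layernorm_bwd(dh2, ln2c)
            grads[f"b{l}_ln2_g"] += dg
            grads[f"b{l}_ln2_b"] += db
            dx = dx + dres
            # attention branch
            dh = self._attn_bwd(dx, attc, l, grads)
            dres, dg, db = _layernorm_bwd(dh, ln1c)
            grads[f"b{l}_ln1_g"] += dg
            grads[f"b{l}_ln1_b"] += db
            dx = dx + dres

        grads["pos"] += dx.sum(axis=0)
        grads["embed_b"] += dx.sum(axis=(0, 1))
        grads["embed_W"] += np.tensordot(tokens, dx, axes=((0, 1), (0, 1)))
        return loss, grads

    def predict_proba(self, tokens: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities, batched to bound memory."""
        out = []
        for i in range(0, tokens.shape[0], batch_size):
            out.append(_softmax(self.forward(tokens[i:i + batch_size])))
        return np.concatenate(out, axis=0) if out else np.zeros((0, self.spec.n_classes))


class Adam:
    """Plain Adam with bias correction; state keyed like the param dict."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def train_vit(
    spec: ViTSpec,
    tokens: np.ndarray,
    labels: np.ndarray,
    epochs: int,
    batch_size: int,
    learning_rate: float,
    seed: int,
) -> TinyViT:
    """Minibatch Adam training; shuffling and init are seed-determined."""
    model = TinyViT(spec, seed=seed)
    opt = Adam(model.params, lr=learning_rate)
    rng = np.random.default_rng(seed + 1)
    n = tokens.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            _, grads = model.loss_and_grads(tokens[idx], labels[idx])
            opt.step(model.params, grads)
    return model
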