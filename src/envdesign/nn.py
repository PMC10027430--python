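"""Minimal numpy neural-network layers with explicit backpropagation.

Supports exactly what the environment classifier needs: dense layers,
post-layer-norm residual transformer blocks with masked multi-head
self-attention, masked mean pooling, softmax cross-entropy, and Adam.
Everything runs in float32 and is deterministic for a fixed seed and
thread-independent input shapes.

Shapes follow the convention (B, K, D): batch of B environments, K
neighbor tokens (padded to the batch maximum), D channels.  ``mask`` is
(B, K) with 1.0 for real neighbors and 0.0 for padding; masked keys get
an additive −1e9 score so their attention weight underflows to exactly
zero, which makes padded and unpadded forward passes identical.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32
NEG_INF = DTYPE(-1e9)
LN_EPS = 1e-5


# ---------------------------------------------------------------------------
# parameter initialization


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


def init_params(
    input_dim: int, model_dim: int, n_layers: int, n_classes: int, seed: int
) -> dict[str, np.ndarray]:
    """Deterministically initialized parameter dictionary."""
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {
        "in.W": glorot(rng, input_dim, model_dim),
        "in.b": np.zeros(model_dim, DTYPE),
    }
    for l in range(n_layers):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"layer{l}.attn.{name}"] = glorot(rng, model_dim, model_dim)
            p[f"layer{l}.attn.{name[0]}b{name[1]}"] = np.zeros(model_dim, DTYPE)
        p[f"layer{l}.ln1.g"] = np.ones(model_dim, DTYPE)
        p[f"layer{l}.ln1.b"] = np.zeros(model_dim, DTYPE)
        p[f"layer{l}.fc.W"] = glorot(rng, model_dim, model_dim)
        p[f"layer{l}.fc.b"] = np.zeros(model_dim, DTYPE)
        p[f"layer{l}.ln2.g"] = np.ones(model_dim, DTYPE)
        p[f"layer{l}.ln2.b"] = np.zeros(model_dim, DTYPE)
    p["head.W"] = glorot(rng, model_dim, n_classes)
    p["head.b"] = np.zeros(n_classes, DTYPE)
    return p


# ---------------------------------------------------------------------------
# primitive forward/backward pairs


def layer_norm_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = xc * inv
    return (xhat * g + b).astype(DTYPE), (xhat, inv, g)


def layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    # reduce over all leading axes
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    return dx.astype(DTYPE), dg.astype(DTYPE), db.astype(DTYPE)


def softmax_last(x):
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def attention_forward(h, mask, p, prefix, n_heads):
    """Masked multi-head self-attention.  Returns output and cache."""
    B, K, D = h.shape
    dh = D // n_heads
    q = h @ p[f"{prefix}.Wq"] + p[f"{prefix}.Wbq"]
    k = h @ p[f"{prefix}.Wk"] + p[f"{prefix}.Wbk"]
    v = h @ p[f"{prefix}.Wv"] + p[f"{prefix}.Wbv"]

    def split(x):  # (B, K, D) -> (B, H, K, dh)
        return x.reshape(B, K, n_heads, dh).transpose(0, 2, 1, 3)

    qh, kh, vh = split(q), split(k), split(v)
    scores = (qh @ kh.transpose(0, 1, 3, 2)) / np.sqrt(DTYPE(dh))
    scores = scores + (1.0 - mask[:, None, None, :]) * NEG_INF
    attn = softmax_last(scores).astype(DTYPE)
    ctx = attn @ vh                                  # (B, H, K, dh)
    merged = ctx.transpose(0, 2, 1, 3).reshape(B, K, D)
    out = merged @ p[f"{prefix}.Wo"] + p[f"{prefix}.Wbo"]
    cache = (h, qh, kh, vh, attn, merged, prefix, n_heads)
    return out.astype(DTYPE), cache


def attention_backward(dout, cache, p, grads):
    h, qh, kh, vh, attn, merged, prefix, n_heads = cache
    B, K, D = h.shape
    dh = D // n_heads

    grads[f"{prefix}.Wo"] += merged.reshape(-1, D).T @ dout.reshape(-1, D)
    grads[f"{prefix}.Wbo"] += dout.sum(axis=(0, 1))
    dmerged = dout @ p[f"{prefix}.Wo"].T
    dctx = dmerged.reshape(B, K, n_heads, dh).transpose(0, 2, 1, 3)

    dattn = dctx @ vh.transpose(0, 1, 3, 2)
    dvh = attn.transpose(0, 1, 3, 2) @ dctx
    # softmax backward (mask preserved: attn is 0 at masked keys)
    dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    dscores = dscores / np.sqrt(DTYPE(dh))
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 1, 3, 2) @ qh

    def merge(x):  # (B, H, K, dh) -> (B, K, D)
        return x.transpose(0, 2, 1, 3).reshape(B, K, D)

    dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
    dhid = np.zeros_like(h)
    for name, dx in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
        grads[f"{prefix}.{name}"] += h.reshape(-1, D).T @ dx.reshape(-1, D)
        grads[f"{prefix}.{name[0]}b{name[1]}"] += dx.sum(axis=(0, 1))
        dhid += dx @ p[f"{prefix}.{name}"].T
    return dhid.astype(DTYPE)


# ---------------------------------------------------------------------------
# full network


def forward(params, X, mask, n_layers, n_heads, want_cache=False):
    """Run the classifier.  Returns (probs, pooled-pre-head, token embeddings, cache)."""
    X = X.astype(DTYPE)
    mask = mask.astype(DTYPE)
    caches = []
    h = (X @ params["in.W"] + params["in.b"]).astype(DTYPE)
    caches.append(("input", X))
    for l in range(n_layers):
        attn_out, attn_cache = attention_forward(
            h, mask, params, f"layer{l}.attn", n_heads
        )
        res1 = h + attn_out
        h1, ln1_cache = layer_norm_forward(
            res1, params[f"layer{l}.ln1.g"], params[f"layer{l}.ln1.b"]
        )
        pre = h1 @ params[f"layer{l}.fc.W"] + params[f"layer{l}.fc.b"]
        relu_mask = pre > 0
        fc = pre * relu_mask
        res2 = h1 + fc
        h2, ln2_cache = layer_norm_forward(
            res2, params[f"layer{l}.ln2.g"], params[f"layer{l}.ln2.b"]
        )
        caches.append((attn_cache, ln1_cache, h1, relu_mask, ln2_cache))
        h = h2.astype(DTYPE)
    counts = mask.sum(axis=1, keepdims=True)
    pooled = (h * mask[:, :, None]).sum(axis=1) / counts
    logits = pooled @ params["head.W"] + params["head.b"]
    probs = softmax_last(logits.astype(np.float64))  # float64 for stable sums
    cache = (caches, h, mask, counts, pooled) if want_cache else None
    return probs, pooled, h, cache


def backward(params, cache, dlogits, n_layers, n_heads):
    """Gradients of a scalar loss with dL/dlogits given."""
    caches, h, mask, counts, pooled = cache
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dlogits = dlogits.astype(DTYPE)
    grads["head.W"] += pooled.T @ dlogits
    grads["head.b"] += dlogits.sum(axis=0)
    dpooled = dlogits @ params["head.W"].T
    dh = (dpooled[:, None, :] * (mask[:, :, None] / counts[:, :, None])).astype(DTYPE)
    for l in range(n_layers - 1, -1, -1):
        attn_cache, ln1_cache, h1, relu_mask, ln2_cache = caches[l + 1]
        dres2, dg2, db2 = layer_norm_backward(dh, ln2_cache)
        grads[f"layer{l}.ln2.g"] += dg2
        grads[f"layer{l}.ln2.b"] += db2
        dfc = dres2 * relu_mask
        D = h1.shape[-1]
        grads[f"layer{l}.fc.W"] += h1.reshape(-1, D).T @ dfc.reshape(-1, D)
        grads[f"layer{l}.fc.b"] += dfc.sum(axis=(0, 1))
        dh1 = dres2 + dfc @ params[f"layer{l}.fc.W"].T
        dres1, dg1, db1 = layer_norm_backward(dh1, ln1_cache)
        grads[f"layer{l}.ln1.g"] += dg1
        grads[f"layer{l}.ln1.b"] += db1
        dattn_in = attention_backward(dres1, attn_cache, params, grads)
        dh = (dres1 + dattn_in).astype(DTYPE)
    X = caches[0][1]
    Din = X.shape[-1]
    grads["in.W"] += X.reshape(-1, Din).T @ dh.reshape(-1, dh.shape[-1])
    grads["in.b"] += dh.sum(axis=(0, 1))
    return grads


def cross_entropy(probs, labels):
    """Mean negative log-likelihood (natural log) and dL/dlogits."""
    n = probs.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(DTYPE)


class Adam:
    """Adam optimizer over a parameter dictionary."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k in params:
            g = grads[k].astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] = (
                params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(DTYPE)
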