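"""A self-contained NumPy transformer encoder with a masked-language-model
head.

Pre-layer-norm architecture: learned token and position embeddings, L
encoder blocks (multi-head self-attention followed by a ReLU
feed-forward layer, both residual), a final layer norm, and a dense
softmax head over the vocabulary that predicts masked tokens.  Forward
and backward passes are written directly against BLAS-backed einsums,
and gradients are exact (verified by finite differences in the test
suite).  All randomness flows through a single seed, so training runs
and fingerprints are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["EncoderConfig", "EncoderModel", "Adam", "MINI", "SPEC_MINI", "PAPER_SCALE"]


@dataclass(frozen=True)
class EncoderConfig:
    vocab_size: int
    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 128
    d_ff: int = 256
    max_len: int = 96
    dtype: str = "float32"
    tie_embeddings: bool = True  # MLM head shares the token embedding

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


def MINI(vocab_size: int) -> EncoderConfig:
    """Desk-scale configuration: trains in minutes on one CPU core."""
    return EncoderConfig(vocab_size, n_layers=2, n_heads=4, d_model=128,
                         d_ff=256, max_len=96)


def SPEC_MINI(vocab_size: int) -> EncoderConfig:
    return EncoderConfig(vocab_size, n_layers=4, n_heads=8, d_model=256,
                         d_ff=1024, max_len=128)


def PAPER_SCALE(vocab_size: int) -> EncoderConfig:
    """The published model geometry (12 encoders, 12 heads, 600-wide
    latents); requires accelerator-scale training."""
    return EncoderConfig(vocab_size, n_layers=12, n_heads=12, d_model=600,
                         d_ff=2400, max_len=512)


def _ln_forward(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _ln_backward(dy, cache):
    xhat, inv, g = cache
    D = xhat.shape[-1]
    dg = (dy * xhat).sum(tuple(range(dy.ndim - 1)))
    db = dy.sum(tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


class EncoderModel:
    """Transformer encoder + MLM head, parameters in a flat dict."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        self.trained = False
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, np.ndarray] = {}

        dt = np.dtype(c.dtype)

        def init(*shape, scale=0.02):
            return (rng.standard_normal(shape) * scale).astype(dt)

        def zeros(*shape):
            return np.zeros(shape, dtype=dt)

        def ones(*shape):
            return np.ones(shape, dtype=dt)

        p["tok_emb"] = init(c.vocab_size, c.d_model)
        p["pos_emb"] = init(c.max_len, c.d_model)
        for l in range(c.n_layers):
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"l{l}.{w}"] = init(c.d_model, c.d_model)
                p[f"l{l}.{w[0]}b{w[1:]}"] = zeros(c.d_model)
            p[f"l{l}.W1"] = init(c.d_model, c.d_ff)
            p[f"l{l}.b1"] = zeros(c.d_ff)
            p[f"l{l}.W2"] = init(c.d_ff, c.d_model)
            p[f"l{l}.b2"] = zeros(c.d_model)
            for ln in ("ln1", "ln2"):
                p[f"l{l}.{ln}_g"] = ones(c.d_model)
                p[f"l{l}.{ln}_b"] = zeros(c.d_model)
        p["lnf_g"] = ones(c.d_model)
        p["lnf_b"] = zeros(c.d_model)
        if not c.tie_embeddings:
            p["mlm_W"] = init(c.d_model, c.vocab_size)
        p["mlm_b"] = zeros(c.vocab_size)
        self.params = p

    # ------------------------------------------------------------------ fwd
    def forward(self, ids: np.ndarray, mask: np.ndarray,
                collect: bool = False, need_cache: bool = False) -> dict:
        """Run the encoder.

        Returns a dict with ``hidden`` (B,T,D) after the final layer
        norm and ``logits`` (B,T,V); with ``collect=True`` also
        ``attn`` (list of (B,H,T,T) row-stochastic matrices) and
        ``ffn`` (list of (B,T,F) post-ReLU activations).
        """
        p, c = self.params, self.config
        ids = np.atleast_2d(ids)
        mask = np.atleast_2d(mask)
        B, T = ids.shape
        if T > c.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {c.max_len}")
        x = p["tok_emb"][ids] + p["pos_emb"][:T]
        key_dtype = x.dtype
        key_bias = ((1.0 - mask[:, None, None, :]) * -1e9).astype(key_dtype)  # (B,1,1,T)
        caches = []
        attns, ffns = [], []
        for l in range(c.n_layers):
            h1, ln1c = _ln_forward(x, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            q = h1 @ p[f"l{l}.Wq"] + p[f"l{l}.Wbq"]
            k = h1 @ p[f"l{l}.Wk"] + p[f"l{l}.Wbk"]
            v = h1 @ p[f"l{l}.Wv"] + p[f"l{l}.Wbv"]

            def split(z):
                return z.reshape(B, T, c.n_heads, c.d_head).transpose(0, 2, 1, 3)

            qh, kh, vh = split(q), split(k), split(v)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(c.d_head) + key_bias
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            attn = e / e.sum(-1, keepdims=True)
            ctx = attn @ vh  # (B,H,T,dh)
            ctx2 = ctx.transpose(0, 2, 1, 3).reshape(B, T, c.d_model)
            attn_out = ctx2 @ p[f"l{l}.Wo"] + p[f"l{l}.Wbo"]
            x = x + attn_out
            h2, ln2c = _ln_forward(x, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            pre = h2 @ p[f"l{l}.W1"] + p[f"l{l}.b1"]
            act = np.maximum(pre, 0.0)
            ffn_out = act @ p[f"l{l}.W2"] + p[f"l{l}.b2"]
            x = x + ffn_out
            if collect:
                attns.append(attn)
                ffns.append(act)
            if need_cache:
                caches.append((h1, ln1c, qh, kh, vh, attn, ctx2, h2, ln2c, act, pre))
        hidden, lnfc = _ln_forward(x, p["lnf_g"], p["lnf_b"])
        head = p["tok_emb"].T if c.tie_embeddings else p["mlm_W"]
        logits = hidden @ head + p["mlm_b"]
        out = {"hidden": hidden, "logits": logits}
        if collect:
            out["attn"] = attns
            out["ffn"] = ffns
        if need_cache:
            out["_cache"] = (ids, mask, caches, lnfc, hidden)
        return out

    # ------------------------------------------------------------ loss/grad
    def loss_and_grads(self, ids, mask, label_pos, label_ids):
        """Masked cross-entropy and exact gradients.

        ``label_pos`` is a boolean (B,T) array marking masked positions
        and ``label_ids`` the original token ids at those positions (in
        row-major order of the mask).
        """
        p, c = self.params, self.config
        out = self.forward(ids, mask, need_cache=True)
        ids2, mask2, caches, lnfc, hidden = out["_cache"]
        B, T = ids2.shape
        logits = out["logits"]
        sel = np.where(label_pos.reshape(-1))[0]
        flat = logits.reshape(-1, c.vocab_size)
        z = flat[sel]
        z = z - z.max(-1, keepdims=True)
        ez = np.exp(z)
        prob = ez / ez.sum(-1, keepdims=True)
        n = sel.size
        nll = -np.log(prob[np.arange(n), label_ids] + 1e-12)
        loss = nll.mean()

        dflat = np.zeros_like(flat)
        dprob = prob.copy()
        dprob[np.arange(n), label_ids] -= 1.0
        dflat[sel] = dprob / n
        dlogits = dflat.reshape(B, T, c.vocab_size)

        g = {k: np.zeros_like(v) for k, v in p.items()}
        head_grad = hidden.reshape(-1, c.d_model).T @ dlogits.reshape(-1, c.vocab_size)
        if c.tie_embeddings:
            g["tok_emb"] += head_grad.T
            head = p["tok_emb"].T
        else:
            g["mlm_W"] = head_grad
            head = p["mlm_W"]
        g["mlm_b"] = dlogits.sum((0, 1))
        dhidden = dlogits @ head.T
        dx, g["lnf_g"], g["lnf_b"] = _ln_backward(dhidden, lnfc)

        for l in range(c.n_layers - 1, -1, -1):
            (h1, ln1c, qh, kh, vh, attn, ctx2, h2, ln2c, act, pre) = caches[l]
            # FFN
            dffn_out = dx
            g[f"l{l}.W2"] += act.reshape(-1, c.d_ff).T @ dffn_out.reshape(-1, c.d_model)
            g[f"l{l}.b2"] += dffn_out.sum((0, 1))
            dact = dffn_out @ p[f"l{l}.W2"].T
            dpre = dact * (pre > 0)
            g[f"l{l}.W1"] += h2.reshape(-1, c.d_model).T @ dpre.reshape(-1, c.d_ff)
            g[f"l{l}.b1"] += dpre.sum((0, 1))
            dh2 = dpre @ p[f"l{l}.W1"].T
            dx2, g[f"l{l}.ln2_g"], g[f"l{l}.ln2_b"] = _ln_backward(dh2, ln2c)
            dx = dx + dx2
            # attention
            dattn_out = dx
            g[f"l{l}.Wo"] += ctx2.reshape(-1, c.d_model).T @ dattn_out.reshape(-1, c.d_model)
            g[f"l{l}.Wbo"] += dattn_out.sum((0, 1))
            dctx2 = dattn_out @ p[f"l{l}.Wo"].T
            dctx = dctx2.reshape(B, T, c.n_heads, c.d_head).transpose(0, 2, 1, 3)
            dattn = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = attn.transpose(0, 1, 3, 2) @ dctx
            dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
            dscores /= np.sqrt(c.d_head)
            dqh = dscores @ kh
            dkh = dscores.transpose(0, 1, 3, 2) @ qh

            def merge(z):
                return z.transpose(0, 2, 1, 3).reshape(B, T, c.d_model)

            dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
            g[f"l{l}.Wq"] += h1.reshape(-1, c.d_model).T @ dq.reshape(-1, c.d_model)
            g[f"l{l}.Wbq"] += dq.sum((0, 1))
            g[f"l{l}.Wk"] += h1.reshape(-1, c.d_model).T @ dk.reshape(-1, c.d_model)
            g[f"l{l}.Wbk"] += dk.sum((0, 1))
            g[f"l{l}.Wv"] += h1.reshape(-1, c.d_model).T @ dv.reshape(-1, c.d_model)
            g[f"l{l}.Wbv"] += dv.sum((0, 1))
            dh1 = dq @ p[f"l{l}.Wq"].T + dk @ p[f"l{l}.Wk"].T + dv @ p[f"l{l}.Wv"].T
            dx1, g[f"l{l}.ln1_g"], g[f"l{l}.ln1_b"] = _ln_backward(dh1, ln1c)
            dx = dx + dx1

        # scatter-add token-embedding gradients (sorted reduceat is much
        # faster than np.add.at for repeated indices)
        flat_ids = ids2.reshape(-1)
        order = np.argsort(flat_ids, kind="stable")
        sorted_ids = flat_ids[order]
        sorted_dx = dx.reshape(-1, c.d_model)[order]
        boundaries = np.flatnonzero(np.r_[True, sorted_ids[1:] != sorted_ids[:-1]])
        sums = np.add.reduceat(sorted_dx, boundaries, axis=0)
        g["tok_emb"][sorted_ids[boundaries]] += sums
        g["pos_emb"][:T] += dx.sum(0)
        return loss, g

    # ---------------------------------------------------------------- io
    def state(self) -> dict:
        return {"config": asdict(self.config), "trained": self.trained,
                "params": self.params}

    def save(self, path) -> None:
        import os

        os.makedirs(path, exist_ok=True)
        np.savez(os.path.join(path, "weights.npz"), **self.params)
        with open(os.path.join(path, "config.json"), "w") as fh:
            json.dump({"config": asdict(self.config), "trained": self.trained}, fh)

    @classmethod
    def load(cls, path) -> "EncoderModel":
        import os

        with open(os.path.join(path, "config.json")) as fh:
            meta = json.load(fh)
        model = cls(EncoderConfig(**meta["config"]))
        with np.load(os.path.join(path, "weights.npz")) as data:
            model.params = {k: data[k] for k in data.files}
        model.trained = meta["trained"]
        return model


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, warmup: int = 100):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.warmup = warmup
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr = self.lr * min(1.0, self.t / max(1, self.warmup))
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
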