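"""BERT-style encoder over protein-token sentences, in NumPy.

The network follows the original transformer encoder: learnable token and
position embedding tables summed into X, a serial stack of post-norm
transformer blocks (multi-head self-attention with padding masked out,
residual + layer normalisation, position-wise two-layer ReLU feed-forward,
residual + layer normalisation), a masked-LM output projection
softmax(Y_i W_d) over the vocabulary, and a classification head
softmax(Y_0 W_p + b_p) on the [CLS] row. Class index 0 = temperate,
index 1 = virulent, fixed repo-wide.

Forward and backward passes are written out explicitly (no autograd
framework); the analytic gradients are validated against finite differences
in the test suite. The paper-scale preset is 512-d, 8 layers, 8 heads; the
desk preset (64-d, 2 layers, 4 heads) is what tests and examples train.

Batched internals crop each batch to its longest attention span before the
attention stack: [PAD] positions beyond it are masked out of attention and
never read by either loss, so the crop changes nothing but speed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .tokenizer import SENTENCE_LENGTH, TokenSentence

__all__ = ["ModelConfig", "ProteinBert", "AdamOptimizer",
           "N_CLASSES", "CLASS_NAMES", "TEMPERATE", "VIRULENT"]

TEMPERATE, VIRULENT = 0, 1
CLASS_NAMES = ("temperate", "virulent")
N_CLASSES = 2

_LN_EPS = 1e-5
_NEG_INF = -1e9


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``d_model`` is the embedding width (default 512), ``n_layers`` the
    number of stacked transformer blocks (default 8) and ``n_heads`` the
    attention head count (default 8). ``ffn_dim`` defaults to 4 x d_model,
    the conventional inner width of the transformer feed-forward network.
    """

    vocab_size: int
    d_model: int = 512
    n_layers: int = 8
    n_heads: int = 8
    max_len: int = SENTENCE_LENGTH
    ffn_dim: int | None = None
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 4 * self.d_model)
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("vocab_size", "d_model", "n_layers", "n_heads",
                     "max_len", "ffn_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def desk(cls, vocab_size: int, **kw) -> "ModelConfig":
        """Small CPU-friendly preset used by tests and examples."""
        kw.setdefault("d_model", 64)
        kw.setdefault("n_layers", 2)
        kw.setdefault("n_heads", 4)
        return cls(vocab_size, **kw)

    @classmethod
    def paper_scale(cls, vocab_size: int, **kw) -> "ModelConfig":
        """Full-scale preset: 512-d, 8 layers, 8 heads."""
        return cls(vocab_size, **kw)

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _layer_norm_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc * xc).mean(axis=-1, keepdims=True) + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy, g, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
                - dxhat.mean(axis=-1, keepdims=True))
    return dx, dg, db


class AdamOptimizer:
    """Adam with bias correction; the paper's optimizer at lr 0.001."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


class ProteinBert:
    """The encoder plus its masked-LM and classification heads."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 params: dict[str, np.ndarray] | None = None):
        self.config = config
        self._drop_rng = np.random.default_rng(seed + 1)
        self.params = params if params is not None else self._init(seed)

    # ------------------------------------------------------------- params
    def _init(self, seed: int) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(seed)

        def w(*shape):
            return rng.normal(0.0, 0.02, size=shape)

        p: dict[str, np.ndarray] = {
            "tok_emb": w(cfg.vocab_size, cfg.d_model),
            "pos_emb": w(cfg.max_len, cfg.d_model),
            "mlm_w": w(cfg.d_model, cfg.vocab_size),
            "cls_w": w(cfg.d_model, N_CLASSES),
            "cls_b": np.zeros(N_CLASSES),
        }
        for l in range(cfg.n_layers):
            p[f"l{l}.wq"] = w(cfg.d_model, cfg.d_model)
            p[f"l{l}.wk"] = w(cfg.d_model, cfg.d_model)
            p[f"l{l}.wv"] = w(cfg.d_model, cfg.d_model)
            p[f"l{l}.wo"] = w(cfg.d_model, cfg.d_model)
            for name in ("bq", "bk", "bv", "bo"):
                p[f"l{l}.{name}"] = np.zeros(cfg.d_model)
            p[f"l{l}.ln1_g"] = np.ones(cfg.d_model)
            p[f"l{l}.ln1_b"] = np.zeros(cfg.d_model)
            p[f"l{l}.w1"] = w(cfg.d_model, cfg.ffn_dim)
            p[f"l{l}.b1"] = np.zeros(cfg.ffn_dim)
            p[f"l{l}.w2"] = w(cfg.ffn_dim, cfg.d_model)
            p[f"l{l}.b2"] = np.zeros(cfg.d_model)
            p[f"l{l}.ln2_g"] = np.ones(cfg.d_model)
            p[f"l{l}.ln2_b"] = np.zeros(cfg.d_model)
        return p

    # ------------------------------------------------------------ dropout
    def _dropout(self, x: np.ndarray, train: bool):
        p = self.config.dropout
        if not train or p == 0.0:
            return x, None
        mask = (self._drop_rng.random(x.shape) >= p) / (1.0 - p)
        return x * mask, mask

    # ------------------------------------------------------------ forward
    def _embed_batch(self, ids: np.ndarray) -> np.ndarray:
        cfg = self.config
        if ids.max() >= cfg.vocab_size or ids.min() < 0:
            bad = np.argwhere((ids >= cfg.vocab_size) | (ids < 0))[0]
            raise ValueError(
                f"token id {ids[tuple(bad)]} at position {tuple(bad)} is "
                f"outside the vocabulary (V={cfg.vocab_size})")
        return self.params["tok_emb"][ids] + self.params["pos_emb"][:ids.shape[1]]

    def _forward_batch(self, ids: np.ndarray, attn_len: np.ndarray,
                       train: bool = False):
        """Encoder forward on (B, L) ids; returns (Y, cache)."""
        cfg, p = self.config, self.params
        B, L = ids.shape
        x = self._embed_batch(ids)
        valid = np.arange(L)[None, :] < attn_len[:, None]       # (B, L) keys
        mask_add = np.where(valid, 0.0, _NEG_INF)[:, None, None, :]
        scale = 1.0 / np.sqrt(cfg.head_dim)
        caches = []
        for l in range(cfg.n_layers):
            x_in = x
            q = x @ p[f"l{l}.wq"] + p[f"l{l}.bq"]
            k = x @ p[f"l{l}.wk"] + p[f"l{l}.bk"]
            v = x @ p[f"l{l}.wv"] + p[f"l{l}.bv"]
            qh = q.reshape(B, L, cfg.n_heads, cfg.head_dim).transpose(0, 2, 1, 3)
            kh = k.reshape(B, L, cfg.n_heads, cfg.head_dim).transpose(0, 2, 1, 3)
            vh = v.reshape(B, L, cfg.n_heads, cfg.head_dim).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) * scale + mask_add
            probs = _softmax(scores)
            probs_d, pmask = self._dropout(probs, train)
            ctx = (probs_d @ vh).transpose(0, 2, 1, 3).reshape(B, L, cfg.d_model)
            o = ctx @ p[f"l{l}.wo"] + p[f"l{l}.bo"]
            o_d, omask = self._dropout(o, train)
            h1, ln1_cache = _layer_norm_forward(
                x_in + o_d, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            z1 = h1 @ p[f"l{l}.w1"] + p[f"l{l}.b1"]
            a1 = np.maximum(z1, 0.0)
            f = a1 @ p[f"l{l}.w2"] + p[f"l{l}.b2"]
            f_d, fmask = self._dropout(f, train)
            x, ln2_cache = _layer_norm_forward(
                h1 + f_d, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            caches.append(dict(x_in=x_in, qh=qh, kh=kh, vh=vh, probs=probs,
                               probs_d=probs_d, pmask=pmask, ctx=ctx,
                               omask=omask, ln1=ln1_cache, h1=h1, z1=z1,
                               a1=a1, fmask=fmask, ln2=ln2_cache))
        if not np.isfinite(x).all():
            raise FloatingPointError("non-finite values in encoder output")
        return x, dict(layers=caches, mask_add=mask_add, scale=scale,
                       ids=ids, B=B, L=L)

    def _backward_batch(self, dY: np.ndarray, cache: dict
                        ) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all encoder + embedding params."""
        cfg, p = self.config, self.params
        B, L = cache["B"], cache["L"]
        scale = cache["scale"]
        grads: dict[str, np.ndarray] = {}
        dx = dY
        for l in reversed(range(cfg.n_layers)):
            c = cache["layers"][l]
            dsum2, dg2, db2 = _layer_norm_backward(dx, p[f"l{l}.ln2_g"], c["ln2"])
            grads[f"l{l}.ln2_g"], grads[f"l{l}.ln2_b"] = dg2, db2
            df = dsum2 if c["fmask"] is None else dsum2 * c["fmask"]
            grads[f"l{l}.w2"] = np.einsum("blf,bld->fd", c["a1"], df)
            grads[f"l{l}.b2"] = df.sum(axis=(0, 1))
            dz1 = (df @ p[f"l{l}.w2"].T) * (c["z1"] > 0)
            grads[f"l{l}.w1"] = np.einsum("bld,blf->df", c["h1"], dz1)
            grads[f"l{l}.b1"] = dz1.sum(axis=(0, 1))
            dh1 = dsum2 + dz1 @ p[f"l{l}.w1"].T
            dsum1, dg1, db1 = _layer_norm_backward(dh1, p[f"l{l}.ln1_g"], c["ln1"])
            grads[f"l{l}.ln1_g"], grads[f"l{l}.ln1_b"] = dg1, db1
            do = dsum1 if c["omask"] is None else dsum1 * c["omask"]
            grads[f"l{l}.wo"] = np.einsum("bld,ble->de", c["ctx"], do)
            grads[f"l{l}.bo"] = do.sum(axis=(0, 1))
            dctx = (do @ p[f"l{l}.wo"].T).reshape(
                B, L, cfg.n_heads, cfg.head_dim).transpose(0, 2, 1, 3)
            dprobs_d = dctx @ c["vh"].transpose(0, 1, 3, 2)
            dvh = c["probs_d"].transpose(0, 1, 3, 2) @ dctx
            dprobs = dprobs_d if c["pmask"] is None else dprobs_d * c["pmask"]
            pr = c["probs"]
            dscores = pr * (dprobs - (dprobs * pr).sum(axis=-1, keepdims=True))
            dqh = dscores @ c["kh"] * scale
            dkh = dscores.transpose(0, 1, 3, 2) @ c["qh"] * scale
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, L, cfg.d_model)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, L, cfg.d_model)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, L, cfg.d_model)
            x_in = c["x_in"]
            grads[f"l{l}.wq"] = np.einsum("bld,ble->de", x_in, dq)
            grads[f"l{l}.wk"] = np.einsum("bld,ble->de", x_in, dk)
            grads[f"l{l}.wv"] = np.einsum("bld,ble->de", x_in, dv)
            grads[f"l{l}.bq"] = dq.sum(axis=(0, 1))
            grads[f"l{l}.bk"] = dk.sum(axis=(0, 1))
            grads[f"l{l}.bv"] = dv.sum(axis=(0, 1))
            dx = (dsum1 + dq @ p[f"l{l}.wq"].T + dk @ p[f"l{l}.wk"].T
                  + dv @ p[f"l{l}.wv"].T)
        grads["tok_emb"] = np.zeros_like(p["tok_emb"])
        np.add.at(grads["tok_emb"], cache["ids"], dx)
        grads["pos_emb"] = np.zeros_like(p["pos_emb"])
        grads["pos_emb"][:L] = dx.sum(axis=0)
        return grads

    # ------------------------------------------------ single-sentence ops
    def embed(self, sentence: TokenSentence | np.ndarray) -> np.ndarray:
        """Embedding matrix X[i] = W_Et[token_ids[i]] + W_Ep[i].

        Accepts a TokenSentence or a raw id vector no longer than max_len.
        """
        ids = (sentence.token_ids if isinstance(sentence, TokenSentence)
               else np.asarray(sentence, dtype=np.int64))
        return self._embed_batch(ids[None, :self.config.max_len])[0]

    def encode(self, X: np.ndarray, attention_length: int) -> np.ndarray:
        """Latent output Y of the transformer stack; same shape as X.

        [PAD] positions beyond ``attention_length`` are masked out of
        attention. Deterministic (dropout off).
        """
        cfg, p = self.config, self.params
        L = X.shape[0]
        # replay the stack on a precomputed embedding (B=1, no dropout)
        saved = self._embed_batch
        try:
            self._embed_batch = lambda ids: X[None]  # type: ignore[assignment]
            Y, _ = self._forward_batch(
                np.zeros((1, L), dtype=np.int64),
                np.array([attention_length]), train=False)
        finally:
            self._embed_batch = saved  # type: ignore[assignment]
        return Y[0]

    def forward_sentence(self, sentence: TokenSentence) -> np.ndarray:
        Y, _ = self._forward_batch(sentence.token_ids[None],
                                   np.array([sentence.attention_length]))
        return Y[0]

    def mlm_logits(self, Y: np.ndarray, positions: Sequence[int]) -> np.ndarray:
        """Per-position probability over the vocabulary: softmax(Y_i W_d)."""
        pos = np.asarray(positions, dtype=np.int64)
        return _softmax(Y[pos] @ self.params["mlm_w"])

    def cls_probs(self, Y: np.ndarray) -> np.ndarray:
        """(temperate, virulent) probabilities: softmax(Y_0 W_p + b_p)."""
        return _softmax(Y[0] @ self.params["cls_w"] + self.params["cls_b"])

    # ------------------------------------------------------ batched heads
    @staticmethod
    def _crop(ids: np.ndarray, attn_len: np.ndarray) -> np.ndarray:
        return ids[:, :int(attn_len.max())]

    def mlm_loss_and_grads(self, ids, attn_len, positions, train=True):
        """Masked-LM cross-entropy, averaged over masked positions.

        ``positions`` is a triple of flat arrays (sample_idx, pos, target):
        the batch row, the in-sentence index and the original token id of
        every masked position.
        """
        sample_idx, pos, tgt = positions
        ids = self._crop(np.asarray(ids), attn_len)
        Y, cache = self._forward_batch(ids, attn_len, train=train)
        yg = Y[sample_idx, pos]                          # (N, D)
        logits = yg @ self.params["mlm_w"]
        probs = _softmax(logits)
        n = len(tgt)
        loss = float(-np.log(probs[np.arange(n), tgt] + 1e-30).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), tgt] -= 1.0
        dlogits /= n
        grads = {"mlm_w": yg.T @ dlogits}
        dY = np.zeros_like(Y)
        np.add.at(dY, (sample_idx, pos), dlogits @ self.params["mlm_w"].T)
        enc_grads = self._backward_batch(dY, cache)
        grads.update(enc_grads)
        grads["cls_w"] = np.zeros_like(self.params["cls_w"])
        grads["cls_b"] = np.zeros_like(self.params["cls_b"])
        return loss, grads

    def mlm_eval_loss(self, ids, attn_len, positions) -> float:
        sample_idx, pos, tgt = positions
        ids = self._crop(np.asarray(ids), attn_len)
        Y, _ = self._forward_batch(ids, attn_len, train=False)
        probs = _softmax(Y[sample_idx, pos] @ self.params["mlm_w"])
        return float(-np.log(probs[np.arange(len(tgt)), tgt] + 1e-30).mean())

    def mlm_predict(self, ids, attn_len, sample_idx, pos) -> np.ndarray:
        """Argmax token id at each masked position."""
        ids = self._crop(np.asarray(ids), attn_len)
        Y, _ = self._forward_batch(ids, attn_len, train=False)
        return np.argmax(Y[sample_idx, pos] @ self.params["mlm_w"], axis=-1)

    def cls_loss_and_grads(self, ids, attn_len, labels, train=True):
        """Classification cross-entropy on the [CLS] row."""
        ids = self._crop(np.asarray(ids), attn_len)
        Y, cache = self._forward_batch(ids, attn_len, train=train)
        y0 = Y[:, 0]
        logits = y0 @ self.params["cls_w"] + self.params["cls_b"]
        probs = _softmax(logits)
        n = len(labels)
        loss = float(-np.log(probs[np.arange(n), labels] + 1e-30).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        grads = {"cls_w": y0.T @ dlogits, "cls_b": dlogits.sum(axis=0)}
        dY = np.zeros_like(Y)
        dY[:, 0] = dlogits @ self.params["cls_w"].T
        grads.update(self._backward_batch(dY, cache))
        grads["mlm_w"] = np.zeros_like(self.params["mlm_w"])
        return loss, grads

    def predict_proba(self, ids, attn_len) -> np.ndarray:
        """(B, 2) class probabilities, deterministic (no dropout)."""
        ids = self._crop(np.asarray(ids), attn_len)
        Y, _ = self._forward_batch(ids, np.asarray(attn_len), train=False)
        return _softmax(Y[:, 0] @ self.params["cls_w"] + self.params["cls_b"])

    # ------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Single-file .npz archive: a JSON config block plus named tensors."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, __config__=np.array(json.dumps(asdict(self.config))),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "ProteinBert":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig(**json.loads(str(data["__config__"])))
            params = {k: data[k].copy() for k in data.files
                      if k != "__config__"}
        return cls(config, seed=seed, params=params)

    def copy(self) -> "ProteinBert":
        return ProteinBert(self.config,
                           params={k: v.copy() for k, v in self.params.items()})
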