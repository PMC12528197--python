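"""Adaptive-attention transformer for EEG epochs, in pure NumPy.

Architecture, per epoch: each channel's frame sequence is linearly
embedded (shared weights by default), summed with a sinusoidal positional
encoding, and passed through a stack of pre-norm encoder layers.  Each
layer applies multi-head temporal self-attention

    A = softmax(Q K^T / sqrt(d_k)),

modulated by a learned adaptive mask M = sigmoid(logits) in (0,1):
attention weights are multiplied elementwise by M and row-renormalized so
the value mixing stays a convex combination.  The mask is trained jointly
with the rest of the network under

    L_mask = sum_ij (1 - M_ij) A_ij    (averaged over heads/layers/batch),

which penalizes attention mass retained in down-weighted regions, plus a
small mean(M) sparsity term so the trivial all-open mask is not optimal.
A position-wise ReLU feed-forward block follows attention in each layer.
Token sequences are mean-pooled per channel; a spatial attention block
over the channel summaries (scaled dot-product similarity, row-softmax)
pools them into one vector, and a softmax head yields class
probabilities.

Both the forward pass and the analytic backward pass are implemented
here; gradients are validated against finite differences in the test
suite.  With dropout disabled every computation is a pure function of
(weights, input), so runs are bit-reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "EEGTransformer",
    "positional_encoding",
    "softmax",
    "masked_attention_weights",
    "mask_loss",
    "spatial_attention",
    "classify",
]

_LN_EPS = 1e-6


# ---------------------------------------------------------------------------
# functional pieces (pure, used by the model and directly testable)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def positional_encoding(seq_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal position matrix: PE[pos, 2i] = sin(pos / 10000^(2i/d)),
    PE[pos, 2i+1] = cos of the same argument."""
    if d_model % 2 != 0:
        raise ValueError("d_model must be even for sin/cos pairing")
    pos = np.arange(seq_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.empty((seq_len, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def masked_attention_weights(
    scores: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row-softmax attention weights, raw and mask-renormalized.

    ``scores`` has queries on axis -2, keys on axis -1.  The masked
    weights are softmax(scores) * mask renormalized per row; computed as
    (exp(scores) * mask) / row-sum, which makes mask == 1 reproduce the
    raw weights bit-for-bit.  A fully masked row falls back to uniform.
    """
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    raw = e / e.sum(axis=-1, keepdims=True)
    if mask is None:
        return raw, raw
    num = e * mask
    denom = num.sum(axis=-1, keepdims=True)
    dead = denom <= np.finfo(float).tiny
    if np.any(dead):
        warnings.warn("fully-masked attention row; falling back to uniform weights")
        num = np.where(dead, 1.0, num)
        denom = np.where(dead, float(scores.shape[-1]), denom)
    return raw, num / denom


def mask_loss(raw_weights: np.ndarray, mask: np.ndarray) -> float:
    """sum_ij (1 - M_ij) A_ij, averaged over all leading axes of A."""
    if raw_weights.shape[-2:] != mask.shape:
        raise ValueError("mask shape must match the attention matrix")
    per_matrix = ((1.0 - mask) * raw_weights).sum(axis=(-2, -1))
    return float(np.mean(per_matrix))


def spatial_attention(summaries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inter-channel attention pooling.

    ``summaries`` is (..., C, d).  Similarity e_ij = u_i . u_j / sqrt(d),
    A_s = row-softmax(e); returns (A_s, pooled) where pooled is the mean
    over i of sum_j A_s[i, j] u_j — one d-vector per leading index.
    """
    if summaries.shape[-2] < 1:
        raise ValueError("need at least one channel")
    d = summaries.shape[-1]
    e = np.einsum("...id,...jd->...ij", summaries, summaries) / np.sqrt(d)
    a_s = softmax(e, axis=-1)
    mixed = np.einsum("...ij,...jd->...id", a_s, summaries)
    return a_s, mixed.mean(axis=-2)


def classify(h: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Softmax head: probabilities over K classes from pooled features."""
    logits = h @ weights + bias
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite classifier logits")
    return softmax(logits, axis=-1)


def _softmax_backward(d_out: np.ndarray, probs: np.ndarray) -> np.ndarray:
    return probs * (d_out - (d_out * probs).sum(axis=-1, keepdims=True))


def _layernorm_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc**2).mean(axis=-1, keepdims=True) + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    dxh = dy * g
    dx = inv * (
        dxh
        - dxh.mean(axis=-1, keepdims=True)
        - xhat * (dxh * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


# ---------------------------------------------------------------------------
# configuration and model


@dataclass
class ModelConfig:
    """Hyperparameters.  Defaults mirror the full-scale configuration
    (6 layers, 8 heads, 256-d); the ablation grid varies heads in
    {4, 8, 12} and depth in {3, 6}."""

    n_layers: int = 6
    n_heads: int = 8
    d_model: int = 256
    d_ff: int | None = None  # defaults to 4 * d_model
    n_classes: int = 2
    n_channels: int = 64
    seq_len: int = 16
    frame_dim: int = 32
    layout: str = "raw_frames"
    mask_lambda: float = 0.1
    mask_sparsity_lambda: float = 0.01
    dropout: float = 0.0
    per_channel_embedding: bool = False
    use_adaptive_mask: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even (positional encoding)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ForwardResult:
    probs: np.ndarray  # B x K
    mask_loss: float
    mean_mask: float
    temporal_raw: list = field(default_factory=list)  # per layer, N x H x P x P
    temporal_masked: list = field(default_factory=list)
    spatial: np.ndarray | None = None  # B x C x C
    caches: dict | None = None

    @property
    def predictions(self) -> np.ndarray:
        return self.probs.argmax(axis=-1)


class EEGTransformer:
    """Pure-NumPy adaptive-attention transformer with analytic gradients."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.pe = positional_encoding(config.seq_len, config.d_model)
        self.params = self._init_params()

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, np.ndarray] = {}

        def xavier(*shape):
            fan_in, fan_out = shape[-2], shape[-1]
            return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape)

        if cfg.per_channel_embedding:
            p["embed.W"] = xavier(cfg.n_channels, cfg.frame_dim, cfg.d_model)
        else:
            p["embed.W"] = xavier(cfg.frame_dim, cfg.d_model)
        p["embed.b"] = np.zeros(cfg.d_model)
        for layer in range(cfg.n_layers):
            k = f"L{layer}."
            p[k + "ln1.g"] = np.ones(cfg.d_model)
            p[k + "ln1.b"] = np.zeros(cfg.d_model)
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[k + name] = xavier(cfg.d_model, cfg.d_model)
            for name in ("bq", "bk", "bv", "bo"):
                p[k + name] = np.zeros(cfg.d_model)
            # sigmoid(2) ~ 0.88: mask starts nearly open
            p[k + "mask.logits"] = np.full((cfg.seq_len, cfg.seq_len), 2.0)
            p[k + "ln2.g"] = np.ones(cfg.d_model)
            p[k + "ln2.b"] = np.zeros(cfg.d_model)
            p[k + "ffn.W1"] = xavier(cfg.d_model, cfg.d_ff)
            p[k + "ffn.b1"] = np.zeros(cfg.d_ff)
            p[k + "ffn.W2"] = xavier(cfg.d_ff, cfg.d_model)
            p[k + "ffn.b2"] = np.zeros(cfg.d_model)
        p["lnf.g"] = np.ones(cfg.d_model)
        p["lnf.b"] = np.zeros(cfg.d_model)
        p["head.W"] = xavier(cfg.d_model, cfg.n_classes)
        p["head.b"] = np.zeros(cfg.n_classes)
        return p

    def mask_matrix(self, layer: int) -> np.ndarray:
        from scipy.special import expit

        return expit(self.params[f"L{layer}.mask.logits"])

    # -- forward ------------------------------------------------------------

    def _split_heads(self, x: np.ndarray) -> np.ndarray:
        n, p_, _ = x.shape
        cfg = self.config
        return x.reshape(n, p_, cfg.n_heads, cfg.d_head).transpose(0, 2, 1, 3)

    def _merge_heads(self, x: np.ndarray) -> np.ndarray:
        n, _, p_, _ = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, p_, self.config.d_model)

    def forward(
        self,
        frames: np.ndarray,
        mask_override: np.ndarray | None = None,
        keep_caches: bool = False,
        collect_attention: bool = False,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> ForwardResult:
        """Run the network on frames of shape (B, C, P, frame_dim)."""
        cfg = self.config
        p = self.params
        b, c, seq, fdim = frames.shape
        if seq != cfg.seq_len or fdim != cfg.frame_dim:
            raise ValueError(
                f"frames (P={seq}, dim={fdim}) do not match config "
                f"(P={cfg.seq_len}, dim={cfg.frame_dim})"
            )
        if c != cfg.n_channels:
            raise ValueError(f"got {c} channels, config expects {cfg.n_channels}")
        use_dropout = train and cfg.dropout > 0
        if use_dropout and dropout_rng is None:
            dropout_rng = np.random.default_rng(cfg.seed)

        if cfg.per_channel_embedding:
            x = np.einsum("bcpf,cfd->bcpd", frames, p["embed.W"]) + p["embed.b"]
        else:
            x = frames @ p["embed.W"] + p["embed.b"]
        x = (x + self.pe).reshape(b * c, seq, cfg.d_model)

        caches: dict = {"frames": frames, "layers": []}
        result = ForwardResult(probs=np.empty(0), mask_loss=0.0, mean_mask=0.0)
        scale = 1.0 / np.sqrt(cfg.d_head)
        total_mask_loss = 0.0
        total_mean_mask = 0.0

        for layer in range(cfg.n_layers):
            k = f"L{layer}."
            lc: dict = {"x_in": x}
            h1, lc["ln1"] = _layernorm_forward(x, p[k + "ln1.g"], p[k + "ln1.b"])
            q = self._split_heads(h1 @ p[k + "Wq"] + p[k + "bq"])
            kk = self._split_heads(h1 @ p[k + "Wk"] + p[k + "bk"])
            v = self._split_heads(h1 @ p[k + "Wv"] + p[k + "bv"])
            scores = np.einsum("nhid,nhjd->nhij", q, kk) * scale
            if mask_override is not None:
                mask = mask_override
            elif cfg.use_adaptive_mask:
                mask = self.mask_matrix(layer)
            else:
                mask = None
            raw, masked = masked_attention_weights(scores, mask)
            o = self._merge_heads(np.einsum("nhij,nhjd->nhid", masked, v))
            o_proj = o @ p[k + "Wo"] + p[k + "bo"]
            if use_dropout:
                keep = (dropout_rng.random(o_proj.shape) >= cfg.dropout) / (1 - cfg.dropout)
                o_proj = o_proj * keep
                lc["drop_attn"] = keep
            x = x + o_proj
            h2, lc["ln2"] = _layernorm_forward(x, p[k + "ln2.g"], p[k + "ln2.b"])
            u1 = h2 @ p[k + "ffn.W1"] + p[k + "ffn.b1"]
            a1 = np.maximum(u1, 0.0)
            f_out = a1 @ p[k + "ffn.W2"] + p[k + "ffn.b2"]
            if use_dropout:
                keep = (dropout_rng.random(f_out.shape) >= cfg.dropout) / (1 - cfg.dropout)
                f_out = f_out * keep
                lc["drop_ffn"] = keep
            x = x + f_out

            m_eff = mask if mask is not None else np.ones((seq, seq))
            total_mask_loss += mask_loss(raw, m_eff)
            total_mean_mask += float(np.mean(m_eff))
            if collect_attention:
                result.temporal_raw.append(raw)
                result.temporal_masked.append(masked)
            if keep_caches:
                lc.update(h1=h1, q=q, k=kk, v=v, raw=raw, masked=masked, mask=m_eff,
                          o_cat=o, h2=h2, u1=u1, a1=a1)
                caches["layers"].append(lc)

        xf, lnf_cache = _layernorm_forward(x, p["lnf.g"], p["lnf.b"])
        u_ch = xf.mean(axis=1).reshape(b, c, cfg.d_model)
        a_s, h_pool = spatial_attention(u_ch)
        probs = classify(h_pool, p["head.W"], p["head.b"])

        result.probs = probs
        result.mask_loss = total_mask_loss / cfg.n_layers
        result.mean_mask = total_mean_mask / cfg.n_layers
        result.spatial = a_s
        if keep_caches:
            caches.update(lnf=lnf_cache, u_ch=u_ch, a_s=a_s, h_pool=h_pool, probs=probs)
            result.caches = caches
        return result

    def predict_proba(self, frames: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = [
            self.forward(frames[i : i + batch_size]).probs
            for i in range(0, len(frames), batch_size)
        ]
        return np.concatenate(out, axis=0)

    # -- loss and gradients -------------------------------------------------

    def loss(self, frames: np.ndarray, labels: np.ndarray) -> dict[str, float]:
        res = self.forward(frames)
        return self._loss_terms(res, labels)

    def _loss_terms(self, res: ForwardResult, labels: np.ndarray) -> dict[str, float]:
        cfg = self.config
        b = len(labels)
        ce = -float(np.mean(np.log(res.probs[np.arange(b), labels] + 1e-300)))
        total = (
            ce
            + cfg.mask_lambda * res.mask_loss
            + cfg.mask_sparsity_lambda * res.mean_mask
        )
        return {
            "total": total,
            "cross_entropy": ce,
            "mask_loss": res.mask_loss,
            "mean_mask": res.mean_mask,
        }

    def loss_and_grads(
        self,
        frames: np.ndarray,
        labels: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[dict[str, float], dict[str, np.ndarray]]:
        """Total loss and analytic gradients for every parameter."""
        cfg = self.config
        p = self.params
        res = self.forward(
            frames, keep_caches=True, train=train, dropout_rng=dropout_rng
        )
        caches = res.caches
        losses = self._loss_terms(res, labels)
        b, c = frames.shape[:2]
        n = b * c
        seq, d = cfg.seq_len, cfg.d_model
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        # classifier head
        dlogits = res.probs.copy()
        dlogits[np.arange(b), labels] -= 1.0
        dlogits /= b
        grads["head.W"] = caches["h_pool"].T @ dlogits
        grads["head.b"] = dlogits.sum(axis=0)
        dh = dlogits @ p["head.W"].T  # B x d

        # spatial attention pooling
        u_ch, a_s = caches["u_ch"], caches["a_s"]
        dv = np.repeat(dh[:, None, :], c, axis=1) / c  # B x C x d
        d_as = np.einsum("bid,bjd->bij", dv, u_ch)
        du = np.einsum("bij,bid->bjd", a_s, dv)
        de = _softmax_backward(d_as, a_s)
        du += (
            np.einsum("bij,bjd->bid", de, u_ch) + np.einsum("bij,bid->bjd", de, u_ch)
        ) / np.sqrt(d)

        # mean-pool over positions, final layernorm
        dxf = np.repeat(du.reshape(n, 1, d), seq, axis=1) / seq
        dx, grads["lnf.g"], grads["lnf.b"] = _layernorm_backward(dxf, caches["lnf"])

        scale = 1.0 / np.sqrt(cfg.d_head)
        adaptive = cfg.use_adaptive_mask
        coef_a = cfg.mask_lambda / (cfg.n_layers * n * cfg.n_heads)
        coef_s = cfg.mask_sparsity_lambda / (cfg.n_layers * seq * seq)

        for layer in reversed(range(cfg.n_layers)):
            k = f"L{layer}."
            lc = caches["layers"][layer]
            # FFN sublayer
            df = dx * lc["drop_ffn"] if "drop_ffn" in lc else dx
            grads[k + "ffn.W2"] = lc["a1"].reshape(-1, cfg.d_ff).T @ df.reshape(-1, d)
            grads[k + "ffn.b2"] = df.sum(axis=(0, 1))
            du1 = (df @ p[k + "ffn.W2"].T) * (lc["u1"] > 0)
            grads[k + "ffn.W1"] = lc["h2"].reshape(-1, d).T @ du1.reshape(-1, cfg.d_ff)
            grads[k + "ffn.b1"] = du1.sum(axis=(0, 1))
            dh2 = du1 @ p[k + "ffn.W1"].T
            dx_mid, grads[k + "ln2.g"], grads[k + "ln2.b"] = _layernorm_backward(
                dh2, lc["ln2"]
            )
            dx = dx + dx_mid

            # attention sublayer
            d_op = dx * lc["drop_attn"] if "drop_attn" in lc else dx
            grads[k + "Wo"] = lc["o_cat"].reshape(-1, d).T @ d_op.reshape(-1, d)
            grads[k + "bo"] = d_op.sum(axis=(0, 1))
            d_oh = self._split_heads(d_op @ p[k + "Wo"].T)  # N,H,P,dh

            masked, raw, mask, v = lc["masked"], lc["raw"], lc["mask"], lc["v"]
            dz = np.einsum("nhid,nhjd->nhij", d_oh, v)
            dv = np.einsum("nhij,nhid->nhjd", masked, d_oh)
            # renormalized masking: Z = (A*M) / row-sum(A*M)
            r = (raw * mask).sum(axis=-1, keepdims=True)
            d_bm = (dz - (dz * masked).sum(axis=-1, keepdims=True)) / r
            d_raw = d_bm * mask
            if adaptive:
                d_mask = (d_bm * raw).sum(axis=(0, 1))
                d_mask -= cfg.mask_lambda / (cfg.n_layers * n * cfg.n_heads) * raw.sum(
                    axis=(0, 1)
                )
                d_mask += coef_s
                grads[k + "mask.logits"] = d_mask * mask * (1.0 - mask)
                d_raw = d_raw + coef_a * (1.0 - mask)
            ds = _softmax_backward(d_raw, raw) * scale
            dq = np.einsum("nhij,nhjd->nhid", ds, lc["k"])
            dk = np.einsum("nhij,nhid->nhjd", ds, lc["q"])
            h1 = lc["h1"].reshape(-1, d)
            dq_m, dk_m, dv_m = (self._merge_heads(a) for a in (dq, dk, dv))
            grads[k + "Wq"] = h1.T @ dq_m.reshape(-1, d)
            grads[k + "Wk"] = h1.T @ dk_m.reshape(-1, d)
            grads[k + "Wv"] = h1.T @ dv_m.reshape(-1, d)
            grads[k + "bq"] = dq_m.sum(axis=(0, 1))
            grads[k + "bk"] = dk_m.sum(axis=(0, 1))
            grads[k + "bv"] = dv_m.sum(axis=(0, 1))
            dh1 = dq_m @ p[k + "Wq"].T + dk_m @ p[k + "Wk"].T + dv_m @ p[k + "Wv"].T
            dx_in, grads[k + "ln1.g"], grads[k + "ln1.b"] = _layernorm_backward(
                dh1, lc["ln1"]
            )
            dx = dx + dx_in

        # embedding
        dx0 = dx.reshape(b, c, seq, d)
        if cfg.per_channel_embedding:
            grads["embed.W"] = np.einsum("bcpf,bcpd->cfd", caches["frames"], dx0)
        else:
            grads["embed.W"] = np.einsum("bcpf,bcpd->fd", caches["frames"], dx0)
        grads["embed.b"] = dx0.sum(axis=(0, 1, 2))
        return losses, grads

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        import json

        arrays = {k.replace(".", "__"): v for k, v in self.params.items()}
        arrays["__config__"] = np.array(json.dumps(self.config.to_dict()))
        classes = getattr(self, "classes_", None)
        if classes is not None:
            arrays["__classes__"] = np.array([str(c) for c in classes])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EEGTransformer":
        import json

        with np.load(path, allow_pickle=False) as f:
            cfg = ModelConfig(**json.loads(str(f["__config__"])))
            model = cls(cfg)
            for key in f.files:
                if key == "__config__":
                    continue
                if key == "__classes__":
                    model.classes_ = [str(c) for c in f[key]]
                    continue
                model.params[key.replace("__", ".")] = f[key]
        return model
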