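"""Time-Series Transformer encoder for PPG-based vitals regression.

An encoder-only transformer over the 4-channel EMD representation of a 20-s
PPG slice.  Per time step the w-channel sample is linearly projected into a
D-dimensional token (z_t = W_p x_t + b_p), a *learnable* positional encoding
W_pos is added, and the sequence passes through post-norm encoder blocks
(multi-head scaled dot-product self-attention and a ReLU feed-forward
sublayer, each followed by layer normalization).  Shorter inputs are padded
to the configured maximum length; a padding mask drives attention scores at
padded key positions to -inf before the softmax and excludes padded
positions from pooling, so predictions are invariant to padding.

Two heads share the encoder:

* a regression head — masked mean-pool over time, a hidden layer of width
  128 with ReLU, and a linear map to one scalar per target (ASBP, ADBP,
  SpO2);
* a masked-reconstruction head — a per-position linear map back to the w
  input channels, trained to reconstruct spans that were zeroed out
  (the masked-value pretraining objective).

Everything is plain NumPy: the forward pass stores the caches needed for an
exact manual backward pass, which is verified against numerical derivatives
in the test suite.  The loss is mean squared error in both modes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "ModelConfig",
    "TimeSeriesTransformer",
    "standardize",
    "destandardize",
    "mask_for_mlm",
    "regression_loss",
    "mlm_loss",
    "save_checkpoint",
    "load_checkpoint",
]

_NEG = -1e30  # effectively -inf for masked attention logits


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 3
    d_model: int = 128
    n_heads: int = 8
    d_ff: int = 256
    head_hidden: int = 128
    dropout: float = 0.1
    max_len: int = 2500
    n_channels: int = 4
    activation: str = "relu"
    targets: tuple[str, ...] = ("ASBP", "ADBP", "SpO2")
    attn_scale: str = "sqrt_dk"  # or "sqrt_len" for the scaling-by-length variant

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by n_heads ({self.n_heads})"
            )
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.activation != "relu":
            raise ValueError("only ReLU activation is supported")
        if self.attn_scale not in ("sqrt_dk", "sqrt_len"):
            raise ValueError("attn_scale must be 'sqrt_dk' or 'sqrt_len'")
        object.__setattr__(self, "targets", tuple(self.targets))

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    @property
    def n_targets(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# Standardization and masking
# ---------------------------------------------------------------------------

def standardize(
    x: np.ndarray, pad_mask: np.ndarray | None = None, eps: float = 1e-12
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-channel standardization of one (w, l) sample over non-padded steps.

    Channels with (near-)zero spread are centered only (an all-zero channel
    passes through as zeros); their recorded sd is 1 so destandardization is
    exact.  Padded positions are zeroed in the output.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (n_channels, length) sample")
    valid = np.ones(x.shape[1], dtype=bool) if pad_mask is None else ~np.asarray(pad_mask)
    if not valid.any():
        raise ValueError("sample has no non-padded positions")
    mean = x[:, valid].mean(axis=1)
    sd = x[:, valid].std(axis=1)
    sd = np.where(sd < eps, 1.0, sd)
    out = (x - mean[:, None]) / sd[:, None]
    out[:, ~valid] = 0.0
    return out, {"mean": mean, "sd": sd}


def destandardize(x_std: np.ndarray, stats: dict[str, np.ndarray]) -> np.ndarray:
    return x_std * stats["sd"][:, None] + stats["mean"][:, None]


def mask_for_mlm(
    x_std: np.ndarray,
    ratio: float,
    mean_span: float = 3.0,
    seed: int | np.random.Generator = 0,
    pad_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out contiguous spans covering ~``ratio`` of the non-padded steps.

    Span lengths are geometric with the given mean; spans are drawn until the
    target count round(ratio * n_valid) is covered, over-shooting spans being
    trimmed, so the masked count is exact whenever enough valid positions
    exist.  Masking zeroes entire time steps (all channels).  Padded
    positions are never masked.  Returns ``(x_masked, mask)`` with ``mask``
    a boolean length-l vector marking exactly the zeroed steps.
    """
    if not 0 <= ratio < 1:
        raise ValueError(f"mask ratio must be in [0, 1), got {ratio}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_std = np.asarray(x_std, dtype=float)
    l = x_std.shape[1]
    valid = np.ones(l, dtype=bool) if pad_mask is None else ~np.asarray(pad_mask)
    mask = np.zeros(l, dtype=bool)
    target = int(round(ratio * valid.sum()))
    if target == 0:
        return x_std.copy(), mask
    valid_idx = np.flatnonzero(valid)
    guard = 0
    while mask.sum() < target and guard < 100 * target:
        guard += 1
        start = int(rng.choice(valid_idx))
        span = 1 + int(rng.geometric(1.0 / mean_span) - 1)
        for pos in range(start, min(l, start + span)):
            if not valid[pos]:
                break
            mask[pos] = True
            if mask.sum() >= target:
                break
    x_masked = x_std.copy()
    x_masked[:, mask] = 0.0
    return x_masked, mask


# ---------------------------------------------------------------------------
# Losses (value + gradient)
# ---------------------------------------------------------------------------

def regression_loss(
    y_hat: np.ndarray, y: np.ndarray, return_grad: bool = False
) -> float | tuple[float, np.ndarray]:
    """MSE over the batch: (1/n) sum_i ||y_hat_i - y_i||^2."""
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    n = y.shape[0]
    diff = y_hat - y
    loss = float(np.sum(diff**2) / n)
    if return_grad:
        return loss, 2.0 * diff / n
    return loss


def mlm_loss(
    predicted: np.ndarray,
    original: np.ndarray,
    mask: np.ndarray,
    return_grad: bool = False,
) -> float | tuple[float, np.ndarray]:
    """Mean squared reconstruction error over MASKED positions only.

    Accepts single samples (w, l) with mask (l,) or batches (B, w, l) with
    mask (B, l).  Unmasked positions contribute nothing to value or gradient.
    """
    predicted = np.asarray(predicted, dtype=float)
    original = np.asarray(original, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if predicted.shape != original.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {original.shape}")
    if mask.sum() == 0:
        raise ValueError("mlm_loss requires a nonempty mask")
    if predicted.ndim == 2:
        m = np.broadcast_to(mask[None, :], predicted.shape)
    else:
        m = np.broadcast_to(mask[:, None, :], predicted.shape)
    n_terms = int(m.sum())
    diff = (predicted - original) * m
    loss = float(np.sum(diff**2) / n_terms)
    if return_grad:
        return loss, 2.0 * diff / n_terms
    return loss


# ---------------------------------------------------------------------------
# Transformer
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _sinusoidal(max_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal table used to *initialize* the learnable positional
    encodings: neighboring positions start out with correlated embeddings,
    which gives attention an immediate handle on locality; training is free
    to reshape the table from there."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return 0.5 * table


def init_params(
    config: ModelConfig, seed: int = 0, dtype=np.float64
) -> dict[str, np.ndarray]:
    """Initialize all learnable tensors (Glorot weights, zero biases,
    small-Gaussian positional encodings, unit layer-norm gains)."""
    rng = np.random.default_rng(seed)
    c = config
    p: dict[str, np.ndarray] = {
        "W_p": _glorot(rng, c.n_channels, c.d_model),
        "b_p": np.zeros(c.d_model),
        "W_pos": _sinusoidal(c.max_len, c.d_model),
    }
    for i in range(c.n_layers):
        # Queries and keys share their initialization: attention then starts
        # as a positive-semidefinite similarity kernel over the (initially
        # sinusoidal) positional code, i.e. with a built-in locality bias
        # that training refines.  The matrices remain independent parameters.
        p[f"L{i}.Wq"] = _glorot(rng, c.d_model, c.d_model)
        p[f"L{i}.Wk"] = p[f"L{i}.Wq"].copy()
        p[f"L{i}.Wv"] = _glorot(rng, c.d_model, c.d_model)
        p[f"L{i}.Wo"] = _glorot(rng, c.d_model, c.d_model)
        p[f"L{i}.bq"] = np.zeros(c.d_model)
        p[f"L{i}.bk"] = np.zeros(c.d_model)
        p[f"L{i}.bv"] = np.zeros(c.d_model)
        p[f"L{i}.bo"] = np.zeros(c.d_model)
        p[f"L{i}.ln1_g"] = np.ones(c.d_model)
        p[f"L{i}.ln1_b"] = np.zeros(c.d_model)
        p[f"L{i}.W1"] = _glorot(rng, c.d_model, c.d_ff)
        p[f"L{i}.b1"] = np.zeros(c.d_ff)
        p[f"L{i}.W2"] = _glorot(rng, c.d_ff, c.d_model)
        p[f"L{i}.b2"] = np.zeros(c.d_model)
        p[f"L{i}.ln2_g"] = np.ones(c.d_model)
        p[f"L{i}.ln2_b"] = np.zeros(c.d_model)
    p["head.W1"] = _glorot(rng, c.d_model, c.head_hidden)
    p["head.b1"] = np.zeros(c.head_hidden)
    p["head.W2"] = _glorot(rng, c.head_hidden, c.n_targets)
    p["head.b2"] = np.zeros(c.n_targets)
    p["mlm.W"] = _glorot(rng, c.d_model, c.n_channels)
    p["mlm.b"] = np.zeros(c.n_channels)
    p["mlm.token"] = rng.normal(0.0, 0.5, size=c.d_model)
    return {k: v.astype(dtype) for k, v in p.items()}


def _layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x - mu) / std
    return xhat * g + b, (xhat, std, g)


def _layernorm_bwd(dy, cache):
    xhat, std, g = cache
    dg = np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
    db = np.sum(dy, axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    ) / std
    return dx, dg, db


def _softmax_lastaxis(s):
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


class TimeSeriesTransformer:
    """Encoder + heads with explicit forward caches and manual backward.

    Parameters live in a flat name -> array dict (``self.params``), which
    optimizers update in place.  ``pad_mask`` is a boolean (B, l) array with
    True at padded positions; the same mask must be passed to forward and
    backward.
    """

    def __init__(
        self,
        config: ModelConfig,
        seed: int = 0,
        params: dict | None = None,
        dtype=np.float64,
    ):
        self.config = config
        self.params = params if params is not None else init_params(config, seed, dtype)

    @property
    def dtype(self):
        return self.params["W_p"].dtype

    def copy(self) -> "TimeSeriesTransformer":
        return TimeSeriesTransformer(
            self.config, params={k: v.copy() for k, v in self.params.items()}
        )

    # -- encoder ----------------------------------------------------------

    def _attention(self, X, pad_mask, i, train, rng):
        c, p = self.config, self.params
        B, l, D = X.shape
        H, dk = c.n_heads, c.d_head
        Q = X @ p[f"L{i}.Wq"] + p[f"L{i}.bq"]
        K = X @ p[f"L{i}.Wk"] + p[f"L{i}.bk"]
        V = X @ p[f"L{i}.Wv"] + p[f"L{i}.bv"]
        split = lambda M: M.reshape(B, l, H, dk).transpose(0, 2, 1, 3)
        Qh, Kh, Vh = split(Q), split(K), split(V)
        scale = float(np.sqrt(dk)) if c.attn_scale == "sqrt_dk" else float(np.sqrt(l))
        # Attention is computed one sample at a time so the (H, l, l) score
        # block stays cache-resident; the softmax runs in place.
        A = np.empty((B, H, l, l), dtype=X.dtype)
        Oh = np.empty_like(Qh)
        masked = pad_mask is not None and bool(pad_mask.any())
        if masked:
            bias = pad_mask.astype(X.dtype) * X.dtype.type(_NEG)  # (B, l)
        for b in range(B):
            S = Qh[b] @ Kh[b].transpose(0, 2, 1)
            S *= 1.0 / scale
            if masked:
                S += bias[b][None, None, :]
            S -= S.max(axis=-1, keepdims=True)
            np.exp(S, out=S)
            S /= S.sum(axis=-1, keepdims=True)
            A[b] = S
            Oh[b] = S @ Vh[b]
        if train and c.dropout > 0:
            keep = rng.random(A.shape, dtype=np.float32) >= c.dropout
            Ad = A * keep / (1.0 - c.dropout)
            for b in range(B):
                Oh[b] = Ad[b] @ Vh[b]
        else:
            keep = None
            Ad = A
        O = Oh.transpose(0, 2, 1, 3).reshape(B, l, D)
        out = O @ p[f"L{i}.Wo"] + p[f"L{i}.bo"]
        cache = (X, Qh, Kh, Vh, A, Ad, keep, O, scale)
        return out, cache

    def _attention_bwd(self, dout, cache, i, grads):
        c, p = self.config, self.params
        X, Qh, Kh, Vh, A, Ad, keep, O, scale = cache
        B, l, D = X.shape
        H, dk = c.n_heads, c.d_head
        grads[f"L{i}.Wo"] += O.reshape(-1, D).T @ dout.reshape(-1, D)
        grads[f"L{i}.bo"] += dout.sum(axis=(0, 1))
        dO = dout @ p[f"L{i}.Wo"].T
        dOh = dO.reshape(B, l, H, dk).transpose(0, 2, 1, 3)
        dQh = np.empty_like(Qh)
        dKh = np.empty_like(Kh)
        dVh = np.empty_like(Vh)
        inv_scale = 1.0 / scale
        for b in range(B):
            dAd = dOh[b] @ Vh[b].transpose(0, 2, 1)
            dVh[b] = Ad[b].transpose(0, 2, 1) @ dOh[b]
            if keep is not None:
                dAd *= keep[b]
                dAd *= 1.0 / (1.0 - c.dropout)
            Ab = A[b]
            row = np.sum(dAd * Ab, axis=-1, keepdims=True)
            dAd -= row
            dAd *= Ab  # now holds dS
            dQh[b] = (dAd @ Kh[b]) * inv_scale
            dKh[b] = (dAd.transpose(0, 2, 1) @ Qh[b]) * inv_scale
        merge = lambda M: M.transpose(0, 2, 1, 3).reshape(B, l, D)
        dQ, dK, dV = merge(dQh), merge(dKh), merge(dVh)
        dX = np.zeros_like(X)
        for name, dM in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            grads[f"L{i}.{name}"] += X.reshape(-1, D).T @ dM.reshape(-1, D)
            grads[f"L{i}.b{name[1]}"] += dM.sum(axis=(0, 1))
            dX += dM @ p[f"L{i}.{name}"].T
        return dX

    def encode(
        self,
        x: np.ndarray,
        pad_mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
        mlm_mask: np.ndarray | None = None,
    ):
        """Embed and encode a batch.

        x : (B, w, l) standardized channel matrices.
        ``mlm_mask`` (B, l) marks masked-for-reconstruction positions, whose
        embeddings receive the learnable mask token — zeroed signal values
        alone are ambiguous (a standardized waveform crosses zero
        constantly), so the token is what tells the encoder where
        reconstruction is required.
        Returns (encoded (B, l, D), cache).
        """
        c, p = self.config, self.params
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        B, w, l = x.shape
        if l > c.max_len:
            raise ValueError(f"sequence length {l} exceeds max_len {c.max_len}")
        if w != c.n_channels:
            raise ValueError(f"expected {c.n_channels} channels, got {w}")
        if pad_mask is not None:
            pad_mask = np.asarray(pad_mask, dtype=bool)
            if pad_mask.ndim == 1:
                pad_mask = pad_mask[None]
            if pad_mask.all(axis=1).any():
                raise ValueError("a sample with all positions padded is invalid")
        if train and rng is None:
            rng = np.random.default_rng(0)
        xt = x.transpose(0, 2, 1)  # (B, l, w)
        Z = xt @ p["W_p"] + p["b_p"] + p["W_pos"][:l]
        if mlm_mask is not None:
            mlm_mask = np.asarray(mlm_mask, dtype=bool)
            if mlm_mask.ndim == 1:
                mlm_mask = mlm_mask[None]
            Z = Z + mlm_mask[:, :, None] * p["mlm.token"]
        layer_caches = []
        h = Z
        for i in range(c.n_layers):
            a, att_cache = self._attention(h, pad_mask, i, train, rng)
            s1 = h + a
            h1, ln1_cache = _layernorm_fwd(s1, p[f"L{i}.ln1_g"], p[f"L{i}.ln1_b"])
            ff_pre = h1 @ p[f"L{i}.W1"] + p[f"L{i}.b1"]
            ff_act = np.maximum(ff_pre, 0.0)
            f = ff_act @ p[f"L{i}.W2"] + p[f"L{i}.b2"]
            s2 = h1 + f
            h2, ln2_cache = _layernorm_fwd(s2, p[f"L{i}.ln2_g"], p[f"L{i}.ln2_b"])
            layer_caches.append((att_cache, ln1_cache, h1, ff_pre, ff_act, ln2_cache))
            h = h2
        cache = {
            "x": x, "xt": xt, "pad_mask": pad_mask, "layers": layer_caches,
            "l": l, "mlm_mask": mlm_mask,
        }
        return h, cache

    def _encode_bwd(self, dh, cache, grads):
        c, p = self.config, self.params
        for i in reversed(range(c.n_layers)):
            att_cache, ln1_cache, h1, ff_pre, ff_act, ln2_cache = cache["layers"][i]
            ds2, dg2, db2 = _layernorm_bwd(dh, ln2_cache)
            grads[f"L{i}.ln2_g"] += dg2
            grads[f"L{i}.ln2_b"] += db2
            df = ds2
            D, F = c.d_model, c.d_ff
            grads[f"L{i}.W2"] += ff_act.reshape(-1, F).T @ df.reshape(-1, D)
            grads[f"L{i}.b2"] += df.sum(axis=(0, 1))
            dff_act = df @ p[f"L{i}.W2"].T
            dff_pre = dff_act * (ff_pre > 0)
            grads[f"L{i}.W1"] += h1.reshape(-1, D).T @ dff_pre.reshape(-1, F)
            grads[f"L{i}.b1"] += dff_pre.sum(axis=(0, 1))
            dh1 = ds2 + dff_pre @ p[f"L{i}.W1"].T
            ds1, dg1, db1 = _layernorm_bwd(dh1, ln1_cache)
            grads[f"L{i}.ln1_g"] += dg1
            grads[f"L{i}.ln1_b"] += db1
            da = ds1
            dh = ds1 + self._attention_bwd(da, att_cache, i, grads)
        # embedding
        l = cache["l"]
        if cache["mlm_mask"] is not None:
            grads["mlm.token"] += dh[cache["mlm_mask"]].sum(axis=0)
        grads["W_pos"][:l] += dh.sum(axis=0)
        xt = cache["xt"]
        w = self.config.n_channels
        grads["W_p"] += xt.reshape(-1, w).T @ dh.reshape(-1, self.config.d_model)
        grads["b_p"] += dh.sum(axis=(0, 1))
        return None

    # -- heads ------------------------------------------------------------

    def predict(
        self,
        x: np.ndarray,
        pad_mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Regression forward: (B, w, l) -> (B, n_targets)."""
        enc, enc_cache = self.encode(x, pad_mask, train, rng)
        p = self.params
        pm = enc_cache["pad_mask"]
        B, l, D = enc.shape
        if pm is None:
            m = np.ones((B, l), dtype=enc.dtype)
        else:
            m = (~pm).astype(enc.dtype)
        counts = m.sum(axis=1, keepdims=True)
        pooled = (enc * m[:, :, None]).sum(axis=1) / counts
        hid_pre = pooled @ p["head.W1"] + p["head.b1"]
        hid = np.maximum(hid_pre, 0.0)
        y = hid @ p["head.W2"] + p["head.b2"]
        if return_cache:
            return y, {
                "enc": enc,
                "enc_cache": enc_cache,
                "m": m,
                "counts": counts,
                "pooled": pooled,
                "hid_pre": hid_pre,
                "hid": hid,
            }
        return y

    def backward_regression(self, dy: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        hid, hid_pre, pooled = cache["hid"], cache["hid_pre"], cache["pooled"]
        grads["head.W2"] += hid.T @ dy
        grads["head.b2"] += dy.sum(axis=0)
        dhid = (dy @ p["head.W2"].T) * (hid_pre > 0)
        grads["head.W1"] += pooled.T @ dhid
        grads["head.b1"] += dhid.sum(axis=0)
        dpooled = dhid @ p["head.W1"].T
        m, counts = cache["m"], cache["counts"]
        denc = dpooled[:, None, :] * (m / counts)[:, :, None]
        self._encode_bwd(denc, cache["enc_cache"], grads)
        return grads

    def reconstruct(
        self,
        x: np.ndarray,
        pad_mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
        mlm_mask: np.ndarray | None = None,
    ):
        """Masked-reconstruction forward: (B, w, l) -> (B, w, l)."""
        enc, enc_cache = self.encode(x, pad_mask, train, rng, mlm_mask=mlm_mask)
        p = self.params
        rec = (enc @ p["mlm.W"] + p["mlm.b"]).transpose(0, 2, 1)  # (B, w, l)
        if return_cache:
            return rec, {"enc": enc, "enc_cache": enc_cache}
        return rec

    def backward_mlm(self, drec: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        enc = cache["enc"]
        B, l, D = enc.shape
        w = self.config.n_channels
        dlin = drec.transpose(0, 2, 1)  # (B, l, w)
        grads["mlm.W"] += enc.reshape(-1, D).T @ dlin.reshape(-1, w)
        grads["mlm.b"] += dlin.sum(axis=(0, 1))
        denc = dlin @ p["mlm.W"].T
        self._encode_bwd(denc, cache["enc_cache"], grads)
        return grads

    def attention_matrices(self, x, pad_mask=None) -> list[np.ndarray]:
        """Per-layer attention weights (B, H, l, l) for inspection/tests."""
        _, cache = self.encode(x, pad_mask, train=False)
        return [layer[0][4] for layer in cache["layers"]]


# ---------------------------------------------------------------------------
# Checkpoints: single-file archive with a config block + named arrays
# ---------------------------------------------------------------------------

def save_checkpoint(model: TimeSeriesTransformer, path, extra: dict | None = None) -> None:
    cfg = asdict(model.config)
    cfg["targets"] = list(cfg["targets"])
    meta = {"config": cfg, "extra": extra or {}}
    import json

    arrays = dict(model.params)
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[TimeSeriesTransformer, dict]:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_d = meta["config"]
    cfg_d["targets"] = tuple(cfg_d["targets"])
    config = ModelConfig(**cfg_d)
    return TimeSeriesTransformer(config, params=params), meta.get("extra", {})
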