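"""Dual-branch hierarchical spectral attention network.

The pipeline, matching the module boundaries used throughout the package:

1. band-token embedding of a global (downsampled full-spectrum) branch and a
   local (selected-band) branch, each token a linear lift of one scalar
   reflectance plus a sinusoidal positional code of its band index;
2. bidirectional cross-attention between the branches (queries from one
   branch, keys/values from the other, both directions);
3. multi-scale average pooling of the token axis, tagging tokens by scale;
4. four role-masked attention heads over the pooled token set (coarsest
   scale only / finest scale within a window / unmasked / cross-scale
   pairs), concatenated and projected, then mean-pooled to a fused vector;
5. hierarchical read-out: a shared ReLU layer feeding a coarse head and a
   fine head, trained with a dynamically weighted joint cross-entropy.

All components can be toggled for ablation: with every flag off the model
reduces to a concatenate-and-MLP baseline over the two branch summaries.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, cross_entropy, layer_norm, relu, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "DBHSNetConfig",
    "DBHSNet",
    "positional_encode",
    "attend",
    "cross_attend",
    "multiscale_pool",
    "msmha_fuse",
    "hcm_forward",
    "dynamic_weight",
    "total_loss",
]

# Additive score mask. -60 drives softmax weights to ~1e-26 (negligible at any
# tolerance we assert) while avoiding the exp underflow slow path that true
# -inf / -1e9 masks trigger on some CPUs.
NEG_MASK = -60.0


@dataclass
class DBHSNetConfig:
    n_bands: int = 750
    local_indices: tuple[int, ...] = ()
    global_tokens: int = 64
    d_model: int = 64
    d_k: int = 16
    n_heads: int = 4
    scales: tuple[int, ...] = (1, 2, 4)
    head_window: float = 64.0  # band-index window for the local-detail head
    n_fine: int = 4
    n_coarse: int = 2
    use_pbca: bool = True
    use_msmha: bool = True
    use_hcm: bool = True
    residual_layernorm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % 2:
            raise ValueError("d_model must be even (sin/cos pairing)")
        if self.use_msmha and self.d_k * self.n_heads != self.d_model:
            raise ValueError("d_k * n_heads must equal d_model")
        if not self.local_indices:
            raise ValueError("model requires a non-empty local band selection")
        if max(self.local_indices) >= self.n_bands or min(self.local_indices) < 0:
            raise ValueError("local band indices out of range for n_bands")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def positional_encode(band_positions: np.ndarray, d_model: int) -> np.ndarray:
    """Sinusoidal position table: row per band, interleaved sin/cos pairs.

    ``out[t, 2i] = sin(x_t / 10000^(2i/d))``, ``out[t, 2i+1]`` the matching
    cosine.
    """
    if d_model % 2:
        raise ValueError("d_model must be even")
    x = np.asarray(band_positions, dtype=float)[:, None]
    i = np.arange(d_model // 2, dtype=float)[None, :]
    angle = x / np.power(10000.0, 2.0 * i / d_model)
    out = np.empty((x.shape[0], d_model))
    out[:, 0::2] = np.sin(angle)
    out[:, 1::2] = np.cos(angle)
    return out


def attend(
    queries: Tensor,
    keys: Tensor,
    values: Tensor,
    w_q: Tensor,
    w_k: Tensor,
    w_v: Tensor,
    w_o: Tensor | None = None,
    additive_mask: np.ndarray | None = None,
):
    """Scaled dot-product attention softmax(QK'/sqrt(d_k))V (+ optional W_O).

    Returns ``(output, attention_weights)`` where the weights are a plain
    ndarray (no gradient) for inspection.
    """
    q = queries @ w_q
    k = keys @ w_k
    v = values @ w_v
    d_k = q.data.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    attn = softmax(scores, additive_mask=additive_mask)
    out = attn @ v
    if w_o is not None:
        out = out @ w_o
    return out, attn.data


def cross_attend(global_tokens: Tensor, local_tokens: Tensor, params: dict,
                 residual_layernorm: bool = True):
    """Bidirectional cross-attention between branches.

    Z_global attends from global queries onto local keys/values and
    Z_local the reverse; each direction has independent projections.
    Residual + layer norm is applied when enabled (off for oracle tests).
    """
    z_g, a_g = attend(global_tokens, local_tokens, local_tokens,
                      params["pbca_g_wq"], params["pbca_g_wk"], params["pbca_g_wv"],
                      params["pbca_g_wo"])
    z_l, a_l = attend(local_tokens, global_tokens, global_tokens,
                      params["pbca_l_wq"], params["pbca_l_wk"], params["pbca_l_wv"],
                      params["pbca_l_wo"])
    if residual_layernorm:
        z_g = layer_norm(global_tokens + z_g)
        z_l = layer_norm(local_tokens + z_l)
    return z_g, z_l, {"attn_global": a_g, "attn_local": a_l}


def _pool_matrix(n_tokens: int, scale: int) -> np.ndarray:
    """Average-pool operator over the token axis, window=stride=scale.

    A trailing partial window is averaged over the tokens it covers.
    """
    n_out = int(np.ceil(n_tokens / scale))
    P = np.zeros((n_out, n_tokens))
    for r in range(n_out):
        lo, hi = r * scale, min((r + 1) * scale, n_tokens)
        P[r, lo:hi] = 1.0 / (hi - lo)
    return P


def multiscale_pool(tokens: Tensor, positions: np.ndarray, scales: tuple[int, ...]):
    """Pool the token axis at each scale and concatenate the pooled sets.

    Returns ``(pooled_tokens, pooled_positions, scale_tags)``; tokens are
    assumed sorted by band position.  Scales larger than the token count are
    skipped with a log entry.
    """
    n_tok = tokens.data.shape[-2]
    parts, pos_parts, tags = [], [], []
    for s in scales:
        if s > n_tok:
            logger.info("multiscale_pool: skipping scale %d (> %d tokens)", s, n_tok)
            continue
        P = _pool_matrix(n_tok, s)
        parts.append(Tensor(P) @ tokens)
        pos_parts.append(P @ np.asarray(positions, dtype=float))
        tags.extend([s] * P.shape[0])
    if not parts:
        raise ValueError("all scales exceed the token count")
    return concat(parts, axis=-2), np.concatenate(pos_parts), np.asarray(tags)


def head_role_masks(positions: np.ndarray, scale_tags: np.ndarray, head_window: float,
                    n_heads: int = 4) -> list[np.ndarray | None]:
    """Additive score masks realizing the four head roles.

    head 1: keys restricted to the coarsest scale (global trend);
    head 2: keys restricted to finest-scale tokens within ``head_window``
            band indices of the query position (local detail);
    head 3: unmasked (long-distance);
    head 4: query and key must come from different scales (cross-scale).
    """
    if n_heads != 4:
        raise ValueError("head roles are defined for exactly 4 heads")
    T = positions.shape[0]
    coarsest, finest = scale_tags.max(), scale_tags.min()
    masks: list[np.ndarray | None] = []

    m1 = np.where(scale_tags[None, :] == coarsest, 0.0, NEG_MASK)
    masks.append(np.broadcast_to(m1, (T, T)).copy())

    near = np.abs(positions[:, None] - positions[None, :]) <= head_window
    m2 = np.where((scale_tags[None, :] == finest) & near, 0.0, NEG_MASK)
    masks.append(m2)

    masks.append(None)

    m4 = np.where(scale_tags[:, None] != scale_tags[None, :], 0.0, NEG_MASK)
    masks.append(m4)

    for h, m in enumerate(masks, start=1):
        if m is not None and (m == NEG_MASK).all(axis=-1).any():
            raise ValueError(f"role mask empties the key set of head {h}")
    return masks


def msmha_fuse(tokens: Tensor, positions: np.ndarray, scale_tags: np.ndarray,
               params: dict, head_window: float = 64.0, n_heads: int = 4,
               vanilla: bool = False, residual_layernorm: bool = True):
    """Role-masked multi-head attention over the multi-scale token set.

    Heads are concatenated and projected by W_O; the mean over output
    tokens is the fused vector.  ``vanilla=True`` disables the role masks.
    """
    masks = [None] * n_heads if vanilla else head_role_masks(positions, scale_tags,
                                                             head_window, n_heads)
    outs, attns = [], []
    for h in range(n_heads):
        out, attn = attend(tokens, tokens, tokens,
                           params[f"msmha_wq{h}"], params[f"msmha_wk{h}"],
                           params[f"msmha_wv{h}"], None, additive_mask=masks[h])
        outs.append(out)
        attns.append(attn)
    fused_tokens = concat(outs, axis=-1) @ params["msmha_wo"]
    if residual_layernorm:
        fused_tokens = layer_norm(tokens + fused_tokens)
    z_fused = fused_tokens.mean(axis=-2)
    return z_fused, {"head_attn": attns}


def hcm_forward(z_fused: Tensor, params: dict, use_hcm: bool = True):
    """Hierarchical read-out: H = ReLU(Z W_shared + b_coarse), then a linear
    coarse head and the fine head Y = H W_fine + b_fine.

    With ``use_hcm=False`` the coarse head is absent (fine logits only).
    """
    h = relu(z_fused @ params["hcm_w_shared"] + params["hcm_b_coarse"])
    if not np.all(np.isfinite(h.data)):
        raise FloatingPointError("NaN/Inf in hierarchical hidden representation")
    fine = h @ params["hcm_w_fine"] + params["hcm_b_fine"]
    coarse = None
    if use_hcm:
        coarse = h @ params["hcm_w_coarse_out"] + params["hcm_b_coarse_out"]
    return coarse, fine


def dynamic_weight(epoch: int, epoch_max: int, l_coarse: float, l_fine: float,
                   mode: str = "blend") -> float:
    """Dynamic coarse-task weight, clipped to [0, 1].

    ``schedule``:      1 - epoch/epoch_max  (coarse emphasis decays);
    ``schedule_raw``:  epoch/epoch_max      (the increasing raw form);
    ``loss_ratio``:    L_coarse / (L_coarse + L_fine);
    ``blend``:         mean of schedule and loss_ratio (default).
    """
    if not (0 <= epoch <= epoch_max):
        raise ValueError("epoch must lie in [0, epoch_max]")
    if l_coarse < 0 or l_fine < 0:
        raise ValueError("losses must be non-negative")
    s = 1.0 - epoch / epoch_max
    if mode == "schedule":
        w = s
    elif mode == "schedule_raw":
        w = epoch / epoch_max
    elif mode == "loss_ratio":
        w = 0.5 if l_coarse + l_fine == 0 else l_coarse / (l_coarse + l_fine)
    elif mode == "blend":
        r = 0.5 if l_coarse + l_fine == 0 else l_coarse / (l_coarse + l_fine)
        w = 0.5 * (s + r)
    else:
        raise ValueError(f"unknown dynamic weight mode {mode!r}")
    return float(min(1.0, max(0.0, w)))


def total_loss(l_coarse, l_fine, w_dynamic: float):
    """Exact convex combination w * L_coarse + (1 - w) * L_fine."""
    if not (0.0 <= w_dynamic <= 1.0):
        raise ValueError("w_dynamic must lie in [0, 1]")
    return l_coarse * w_dynamic + l_fine * (1.0 - w_dynamic)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DBHSNet:
    """Parameter container + forward pass.  Training lives in ``training``."""

    def __init__(self, config: DBHSNetConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._init_params()
        # precompute global branch pooling groups and token positions
        edges = np.linspace(0, config.n_bands, config.global_tokens + 1).astype(int)
        self._global_groups = [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]
        self._global_positions = np.array([(a + b - 1) / 2.0 for a, b in self._global_groups])
        order = np.argsort(np.asarray(config.local_indices, dtype=float), kind="stable")
        self._local_order = order
        self._local_positions = np.asarray(config.local_indices, dtype=float)[order]

    # -- parameters --------------------------------------------------------
    def _add_param(self, rng: np.random.Generator, name: str, shape: tuple[int, ...]) -> None:
        fan_in = shape[0] if len(shape) > 1 else max(1, shape[0])
        scale = 1.0 / np.sqrt(fan_in)
        self.params[name] = Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)

    def _init_params(self) -> None:
        c = self.config
        rng = np.random.default_rng(c.seed)
        d, dk = c.d_model, c.d_k
        self._add_param(rng, "embed_g_w", (1, d))
        self._add_param(rng, "embed_g_b", (d,))
        self._add_param(rng, "embed_l_w", (1, d))
        self._add_param(rng, "embed_l_b", (d,))
        for side in ("g", "l"):
            self._add_param(rng, f"pbca_{side}_wq", (d, dk))
            self._add_param(rng, f"pbca_{side}_wk", (d, dk))
            self._add_param(rng, f"pbca_{side}_wv", (d, dk))
            self._add_param(rng, f"pbca_{side}_wo", (dk, d))
        for h in range(c.n_heads):
            self._add_param(rng, f"msmha_wq{h}", (d, dk))
            self._add_param(rng, f"msmha_wk{h}", (d, dk))
            self._add_param(rng, f"msmha_wv{h}", (d, dk))
        self._add_param(rng, "msmha_wo", (c.n_heads * dk, d))
        self._add_param(rng, "fuse_w", (2 * d, d))
        self._add_param(rng, "fuse_b", (d,))
        self._add_param(rng, "hcm_w_shared", (d, d))
        self._add_param(rng, "hcm_b_coarse", (d,))
        self._add_param(rng, "hcm_w_coarse_out", (d, c.n_coarse))
        self._add_param(rng, "hcm_b_coarse_out", (c.n_coarse,))
        self._add_param(rng, "hcm_w_fine", (d, c.n_fine))
        self._add_param(rng, "hcm_b_fine", (c.n_fine,))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    # -- branch construction -----------------------------------------------
    def branch_inputs(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a samples x bands matrix into (global, local) branch values."""
        values = np.asarray(values, dtype=float)
        if values.shape[1] != self.config.n_bands:
            raise ValueError(
                f"model built for {self.config.n_bands} bands, got {values.shape[1]}"
            )
        g = np.stack([values[:, a:b].mean(axis=1) for a, b in self._global_groups], axis=1)
        sel = np.asarray(self.config.local_indices)[self._local_order]
        return g, values[:, sel]

    def _embed(self, x: np.ndarray, positions: np.ndarray, side: str, use_pe: bool) -> Tensor:
        t = Tensor(x[:, :, None]) @ self.params[f"embed_{side}_w"] + self.params[f"embed_{side}_b"]
        if use_pe:
            t = t + Tensor(positional_encode(positions, self.config.d_model))
        return t

    # -- forward -----------------------------------------------------------
    def forward(self, x_global: np.ndarray, x_local: np.ndarray,
                local_positions: np.ndarray | None = None, collect_aux: bool = False):
        """Run the dual-branch pipeline on branch value matrices.

        ``x_global``/``x_local`` are samples x branch-band matrices;
        ``local_positions`` defaults to the model's sorted selection.
        Returns ``(coarse_logits, fine_logits)`` Tensors (coarse is None
        when the hierarchy is disabled), plus an aux dict when requested.
        """
        c = self.config
        gpos = self._global_positions
        lpos = self._local_positions if local_positions is None else np.asarray(local_positions, float)
        if x_local.shape[1] != lpos.shape[0]:
            raise ValueError("local branch width does not match its positions")
        # canonical order: tokens sorted by band position (makes the forward
        # invariant to the order local bands are supplied in)
        lorder = np.argsort(lpos, kind="stable")
        lpos = lpos[lorder]
        x_local = np.asarray(x_local, dtype=float)[:, lorder]

        tok_g = self._embed(np.asarray(x_global, float), gpos, "g", use_pe=c.use_pbca)
        tok_l = self._embed(x_local, lpos, "l", use_pe=c.use_pbca)

        aux: dict = {}
        if c.use_pbca:
            z_g, z_l, a = cross_attend(tok_g, tok_l, self.params, c.residual_layernorm)
            aux.update(a)
        else:
            z_g, z_l = tok_g, tok_l

        if c.use_msmha:
            pg, pos_g, tag_g = multiscale_pool(z_g, gpos, c.scales)
            pl, pos_l, tag_l = multiscale_pool(z_l, lpos, c.scales)
            tokens = concat([pg, pl], axis=-2)
            positions = np.concatenate([pos_g, pos_l])
            tags = np.concatenate([tag_g, tag_l])
            z_fused, a = msmha_fuse(tokens, positions, tags, self.params,
                                    head_window=c.head_window, n_heads=c.n_heads,
                                    residual_layernorm=c.residual_layernorm)
            aux.update(a)
        else:
            # concatenate-and-project baseline over the two branch summaries
            summary = concat([z_g.mean(axis=-2), z_l.mean(axis=-2)], axis=-1)
            z_fused = summary @ self.params["fuse_w"] + self.params["fuse_b"]

        coarse, fine = hcm_forward(z_fused, self.params, use_hcm=c.use_hcm)
        if collect_aux:
            return coarse, fine, aux
        return coarse, fine

    def forward_spectra(self, values: np.ndarray, collect_aux: bool = False):
        """Forward a full samples x bands matrix (branch split done here)."""
        g, l = self.branch_inputs(values)
        return self.forward(g, l, collect_aux=collect_aux)

    def predict(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Fine (and coarse, if present) argmax class indices."""
        coarse, fine = self.forward_spectra(values)
        fine_pred = fine.data.argmax(axis=1)
        coarse_pred = None if coarse is None else coarse.data.argmax(axis=1)
        return fine_pred, coarse_pred

    def loss(self, values: np.ndarray, fine_labels: np.ndarray,
             coarse_labels: np.ndarray | None, w_dynamic: float):
        """Joint loss Tensor plus the two component losses (floats, nats)."""
        coarse_logits, fine_logits = self.forward_spectra(values)
        l_fine = cross_entropy(fine_logits, fine_labels)
        if coarse_logits is None or coarse_labels is None:
            return l_fine, float("nan"), float(l_fine.data)
        l_coarse = cross_entropy(coarse_logits, coarse_labels)
        joint = total_loss(l_coarse, l_fine, w_dynamic)
        return joint, float(l_coarse.data), float(l_fine.data)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=float)

    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg["local_indices"] = list(cfg["local_indices"])
        cfg["scales"] = list(cfg["scales"])
        np.savez(path, __config__=np.array([repr(cfg)], dtype=object),
                 **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "DBHSNet":
        import ast

        with np.load(path, allow_pickle=True) as z:
            cfg = ast.literal_eval(str(z["__config__"][0]))
            cfg["local_indices"] = tuple(cfg["local_indices"])
            cfg["scales"] = tuple(cfg["scales"])
            model = cls(DBHSNetConfig(**cfg))
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model
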