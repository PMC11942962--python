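"""Transformer encoder with sequence-structure disentangled attention.

Each residue position carries three representations: its residue-token
content S, its structure-token content ST, and a relative-position embedding
P indexed by the clipped signed offset between positions. A full cross
attention between the triples factorizes into nine bilinear components; the
four components that pair structure or position with itself are dropped,
leaving five retained interaction types:

    residue-to-residue     Q_s,i . K_s,j
    residue-to-structure   Q_s,i . K_st,j
    residue-to-position    Q_s,i . K_p,delta(i,j)
    structure-to-residue   Q_st,i . K_s,j
    position-to-residue    Q_p,delta(j,i) . K_s,j

Scores are scaled by 1/sqrt(5 d) — one sqrt(d) factor per retained term, the
disentangled-attention convention — before the softmax, and only the residue
content stream carries values: H_0 = softmax(A^ / sqrt(5 d)) V_s. The residue
stream evolves through the layer stack; structure and position embeddings are
static inputs to every layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .core import RESIDUE_PAD, RESIDUE_VOCAB, TokenizedProtein
from .nn import (
    AdamW,
    Embedding,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    linear_warmup,
)

__all__ = [
    "EncoderConfig",
    "SSTEncoder",
    "relative_position_index",
    "relative_index_matrix",
    "pad_token_batch",
    "mlm_pretrain",
    "ALL_INTERACTIONS",
    "RETAINED_INTERACTIONS",
]

_STREAMS = ("residue", "structure", "position")

#: The nine bilinear components of the factorized cross attention.
ALL_INTERACTIONS: tuple[tuple[str, str], ...] = tuple(product(_STREAMS, _STREAMS))

#: The five retained interaction types (structure-structure,
#: structure-position, position-structure and position-position are removed).
RETAINED_INTERACTIONS: tuple[tuple[str, str], ...] = (
    ("residue", "residue"),
    ("residue", "structure"),
    ("residue", "position"),
    ("structure", "residue"),
    ("position", "residue"),
)

_NEG_INF = -1e9


@dataclass
class EncoderConfig:
    """Hyperparameters of the disentangled-attention encoder."""

    d_model: int = 32
    n_heads: int = 4
    n_layers: int = 2
    n_structure_vocab: int = 64  # structure vocabulary K (padding id appended)
    r_max: int = 64
    dropout: float = 0.0
    ff_dim: int = 64
    n_residue_vocab: int = RESIDUE_VOCAB

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    @property
    def structure_pad(self) -> int:
        return self.n_structure_vocab

    @property
    def n_position(self) -> int:
        return 2 * self.r_max + 1


def relative_position_index(i: int, j: int, r_max: int) -> int:
    """Table index of the relative position of key j with respect to query i:
    ``clip(j - i, -r_max, r_max) + r_max``."""
    return int(np.clip(j - i, -r_max, r_max) + r_max)


def relative_index_matrix(L: int, r_max: int) -> np.ndarray:
    """(L, L) matrix of relative-position table indices, entry (i, j)."""
    offs = np.arange(L)[None, :] - np.arange(L)[:, None]
    return (np.clip(offs, -r_max, r_max) + r_max).astype(np.intp)


class DisentangledAttention(Module):
    """Multi-head five-term disentangled attention."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.d_model
        # bias-free projections so zeroed structure/position embeddings
        # nullify their terms exactly
        self.Wq_s = Linear(d, d, rng, bias=False)
        self.Wk_s = Linear(d, d, rng, bias=False)
        self.Wv_s = Linear(d, d, rng, bias=False)
        self.Wq_st = Linear(d, d, rng, bias=False)
        self.Wk_st = Linear(d, d, rng, bias=False)
        self.Wq_p = Linear(d, d, rng, bias=False)
        self.Wk_p = Linear(d, d, rng, bias=False)
        self.out_proj = Linear(d, d, rng)

    def _heads(self, x: Tensor, B: int, L: int) -> Tensor:
        c = self.config
        return x.reshape(B, L, c.n_heads, c.d_head).swapaxes(1, 2)

    def _pos_heads(self, x: Tensor) -> Tensor:
        c = self.config
        return x.reshape(c.n_position, c.n_heads, c.d_head).swapaxes(0, 1)

    def scores(self, S: Tensor, ST: Tensor, P: Tensor) -> Tensor:
        """Unscaled per-head score matrices, shape (B, n_heads, L, L)."""
        B, L, _ = S.shape
        c = self.config
        Qs = self._heads(self.Wq_s(S), B, L)
        Ks = self._heads(self.Wk_s(S), B, L)
        Qst = self._heads(self.Wq_st(ST), B, L)
        Kst = self._heads(self.Wk_st(ST), B, L)
        Qp = self._pos_heads(self.Wq_p(P))  # (H, 2r+1, dh)
        Kp = self._pos_heads(self.Wk_p(P))
        idx = relative_index_matrix(L, c.r_max)

        c2c = Qs @ Ks.swapaxes(-1, -2)
        c2st = Qs @ Kst.swapaxes(-1, -2)
        st2c = Qst @ Ks.swapaxes(-1, -2)
        # residue-to-position: lookup column delta(i, j) of Qs Kp^T
        c2p = (Qs @ Kp.swapaxes(-1, -2)).gather_last(idx)
        # position-to-residue: (Ks Qp^T)[j, delta(j, i)], then transpose j<->i
        p2c = (Ks @ Qp.swapaxes(-1, -2)).gather_last(idx).swapaxes(-1, -2)
        return c2c + c2st + c2p + st2c + p2c

    def __call__(self, S: Tensor, ST: Tensor, P: Tensor, mask: np.ndarray) -> Tensor:
        B, L, _ = S.shape
        c = self.config
        mask = np.asarray(mask, dtype=np.float64)
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("a sequence in the batch has every key position masked")
        raw = self.scores(S, ST, P)
        scaled = raw * (1.0 / np.sqrt(5.0 * c.d_head))
        key_bias = Tensor((1.0 - mask)[:, None, None, :] * _NEG_INF)
        attn = (scaled + key_bias).softmax(axis=-1)
        Vs = self._heads(self.Wv_s(S), B, L)
        out = (attn @ Vs).swapaxes(1, 2).reshape(B, L, c.d_model)
        out = self.out_proj(out)
        # zero padded query rows
        return out * Tensor(mask[:, :, None])


class _EncoderLayer(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = DisentangledAttention(config, rng)
        self.norm1 = LayerNorm(config.d_model)
        self.norm2 = LayerNorm(config.d_model)
        self.ff1 = Linear(config.d_model, config.ff_dim, rng)
        self.ff2 = Linear(config.ff_dim, config.d_model, rng)

    def __call__(self, x: Tensor, ST: Tensor, P: Tensor, mask: np.ndarray, drop) -> Tensor:
        x = x + drop(self.attn(self.norm1(x), ST, P, mask))
        x = x + drop(self.ff2(self.ff1(self.norm2(x)).gelu()))
        return x


class SSTEncoder(Module):
    """Stacked disentangled-attention encoder over parallel token streams."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.residue_embedding = Embedding(config.n_residue_vocab, config.d_model, rng)
        # +1 slot for the structure padding id
        self.structure_embedding = Embedding(config.n_structure_vocab + 1, config.d_model, rng)
        self.position_embedding = Tensor(
            np.random.default_rng(seed + 1).normal(0, 0.02, size=(config.n_position, config.d_model)),
            requires_grad=True,
        )
        self.layers = [_EncoderLayer(config, rng) for _ in range(config.n_layers)]
        self.final_norm = LayerNorm(config.d_model)
        self.mlm_head = Linear(config.d_model, 21, rng)  # predicts residue letters only
        self._drop_rng = np.random.default_rng(seed + 2)

    # -- embedding ------------------------------------------------------------
    def embed_inputs(
        self, residue_ids: np.ndarray, structure_ids: np.ndarray
    ) -> tuple[Tensor, Tensor, Tensor, np.ndarray]:
        """Token ids (B, L) -> (S, ST, P, padding mask)."""
        residue_ids = np.asarray(residue_ids)
        structure_ids = np.asarray(structure_ids)
        c = self.config
        if residue_ids.max() >= c.n_residue_vocab or residue_ids.min() < 0:
            raise ValueError("residue token id out of vocabulary")
        if structure_ids.max() > c.structure_pad or structure_ids.min() < 0:
            raise ValueError("structure token id out of vocabulary")
        S = self.residue_embedding(residue_ids)
        ST = self.structure_embedding(structure_ids)
        mask = (residue_ids != RESIDUE_PAD).astype(np.float64)
        return S, ST, self.position_embedding, mask

    def _dropout(self, x: Tensor) -> Tensor:
        rate = self.config.dropout
        if not self.training or rate <= 0:
            return x
        keep = (self._drop_rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(keep)

    def forward(self, residue_ids: np.ndarray, structure_ids: np.ndarray) -> Tensor:
        """(B, L) token ids -> (B, L, d_model) representations.

        Padded positions are masked out of attention and zeroed in the output.
        """
        S, ST, P, mask = self.embed_inputs(residue_ids, structure_ids)
        x = S
        for layer in self.layers:
            x = layer(x, ST, P, mask, self._dropout)
        x = self.final_norm(x)
        return x * Tensor(mask[:, :, None])

    # -- masked-language-model pretraining ------------------------------------
    def mlm_step_loss(
        self,
        residue_ids: np.ndarray,
        structure_ids: np.ndarray,
        mask_rate: float,
        rng: np.random.Generator,
    ) -> Tensor:
        """Cross-entropy over masked residue positions.

        Residue tokens are replaced by the mask symbol at rate ``mask_rate``
        (at least one position per batch); structure tokens are never masked.
        """
        if not 0 < mask_rate < 1:
            raise ValueError("mask_rate must lie in (0, 1)")
        residue_ids = np.asarray(residue_ids)
        valid = residue_ids != RESIDUE_PAD
        if not valid.any():
            raise ValueError("batch has zero maskable positions")
        from .core import RESIDUE_MASK

        chosen = (rng.random(residue_ids.shape) < mask_rate) & valid
        if not chosen.any():
            flat_valid = np.flatnonzero(valid.ravel())
            pick = flat_valid[rng.integers(len(flat_valid))]
            chosen = np.zeros_like(valid)
            chosen.ravel()[pick] = True
        corrupted = np.where(chosen, RESIDUE_MASK, residue_ids)
        H = self.forward(corrupted, structure_ids)
        rows, cols = np.nonzero(chosen)
        logits = self.mlm_head(H[rows, cols, :])  # (M, 21)
        targets = residue_ids[rows, cols][:, None]
        shifted = logits + Tensor(-logits.data.max(axis=-1, keepdims=True))
        logz = shifted.exp().sum(axis=-1, keepdims=True).log()
        nll = (logz - shifted.gather_last(targets)).mean()
        return nll


def pad_token_batch(
    tokens: list[TokenizedProtein], structure_pad: int
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad a list of token sequences into (B, Lmax) id arrays."""
    L = max(len(t) for t in tokens)
    res = np.full((len(tokens), L), RESIDUE_PAD, dtype=np.int64)
    st = np.full((len(tokens), L), structure_pad, dtype=np.int64)
    for b, t in enumerate(tokens):
        res[b, : len(t)] = t.residue_tokens
        st[b, : len(t)] = t.structure_tokens
    return res, st


def mlm_pretrain(
    model: SSTEncoder,
    tokens: list[TokenizedProtein],
    steps: int,
    mask_rate: float,
    rng: np.random.Generator,
    batch_size: int = 8,
    lr: float = 1e-3,
) -> list[float]:
    """Masked-residue language-model pretraining; returns per-step losses."""
    model.train()
    opt = AdamW(model.parameters(), lr=lr)
    losses: list[float] = []
    n = len(tokens)
    for step in range(steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        batch = [tokens[i] for i in idx]
        res, st = pad_token_batch(batch, model.config.structure_pad)
        loss = model.mlm_step_loss(res, st, mask_rate, rng)
        opt.zero_grad()
        loss.backward()
        opt.set_lr(linear_warmup(step, steps, lr))
        opt.step()
        losses.append(loss.item())
    model.eval()
    return losses
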