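"""Joint sequence-structure multi-label classifier.

Couples the disentangled-attention encoder with the multi-scale residual head
and trains them end to end with per-task binary cross-entropy. After each
epoch the validation Fmax is computed and the parameters with the highest
validation Fmax are the ones retained — test predictions always come from
that checkpoint.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .core import LabelTable, TokenizedProtein
from .encoder import EncoderConfig, SSTEncoder, mlm_pretrain, pad_token_batch
from .head import HeadConfig, MultiScaleHead
from .metrics import PredictionTable, fmax
from .nn import AdamW, Tensor, linear_warmup, no_grad

__all__ = ["SequenceStructureClassifier", "select_best_checkpoint"]


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits."""
    y = Tensor(np.asarray(targets, dtype=np.float64))
    return (logits.relu() - logits * y + (1.0 + (-logits.abs()).exp()).log()).mean()


def select_best_checkpoint(history: list[dict]) -> int:
    """Earliest epoch index achieving the maximum validation Fmax."""
    if not history:
        raise ValueError("empty training log")
    val = [h["val_fmax"] for h in history]
    return int(np.argmax(val))  # argmax returns the first maximum


class SequenceStructureClassifier(BaseEstimator):
    """Multi-label protein property classifier over parallel token streams.

    Parameters
    ----------
    n_structure_vocab : int
        Structure vocabulary size K of the tokenizer codebook.
    d_model, n_heads, n_layers, r_max, ff_dim, dropout
        Encoder hyperparameters.
    kernel_sizes, depth, ablation_mode
        Multi-scale head hyperparameters (``ablation_mode`` one of ``full``,
        ``single_kernel:k``, ``embedding_only``).
    constant_structure : bool
        Control setting: replace every structure token with a single constant
        token, severing the structure pathway while keeping the architecture
        and parameter count identical.
    freeze_encoder : bool
        Train only the head on frozen (typically MLM-pretrained) encoder
        representations; the per-protein representations are cached once, so
        head-only training is cheap. Used by the head-ablation experiments.
    mlm_steps : int
        Masked-residue language-model pretraining steps before supervised
        training (0 disables).
    epochs, batch_size, lr, weight_decay, warmup_frac
        AdamW optimization settings (linear warmup).
    seed : int
        Single seed from which all randomness (initialization, batching,
        masking, dropout) derives.
    """

    def __init__(
        self,
        n_structure_vocab: int = 64,
        d_model: int = 32,
        n_heads: int = 4,
        n_layers: int = 2,
        r_max: int = 64,
        ff_dim: int = 64,
        dropout: float = 0.0,
        kernel_sizes: tuple[int, ...] = (3, 5, 7),
        depth: int = 2,
        ablation_mode: str = "full",
        constant_structure: bool = False,
        mlm_steps: int = 0,
        mlm_mask_rate: float = 0.15,
        freeze_encoder: bool = False,
        epochs: int = 30,
        batch_size: int = 16,
        lr: float = 3e-3,
        weight_decay: float = 0.01,
        warmup_frac: float = 0.05,
        seed: int = 0,
    ):
        self.n_structure_vocab = n_structure_vocab
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.r_max = r_max
        self.ff_dim = ff_dim
        self.dropout = dropout
        self.kernel_sizes = kernel_sizes
        self.depth = depth
        self.ablation_mode = ablation_mode
        self.constant_structure = constant_structure
        self.mlm_steps = mlm_steps
        self.mlm_mask_rate = mlm_mask_rate
        self.freeze_encoder = freeze_encoder
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.warmup_frac = warmup_frac
        self.seed = seed

    # -- construction ---------------------------------------------------------
    def _build(self, n_tasks: int) -> None:
        enc_cfg = EncoderConfig(
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            n_structure_vocab=self.n_structure_vocab,
            r_max=self.r_max,
            dropout=self.dropout,
            ff_dim=self.ff_dim,
        )
        head_cfg = HeadConfig(
            d_model=self.d_model,
            n_tasks=n_tasks,
            kernel_sizes=tuple(self.kernel_sizes),
            depth=self.depth,
            ablation_mode=self.ablation_mode,
        )
        self.encoder_ = SSTEncoder(enc_cfg, seed=self.seed)
        self.head_ = MultiScaleHead(head_cfg, rng=np.random.default_rng(self.seed + 1))
        self.n_tasks_ = n_tasks

    def _batch_arrays(self, tokens: list[TokenizedProtein]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        from .core import RESIDUE_PAD

        res, st = pad_token_batch(tokens, self.encoder_.config.structure_pad)
        if self.constant_structure:
            st = np.where(st == self.encoder_.config.structure_pad, st, 0)
        mask = (res != RESIDUE_PAD).astype(np.float64)
        return res, st, mask

    # -- training -------------------------------------------------------------
    def fit(
        self,
        X: list[TokenizedProtein],
        y: LabelTable,
    ) -> "SequenceStructureClassifier":
        """Train on the LabelTable's train split, select by validation Fmax."""
        by_id = {t.id: t for t in X}
        split = y.split or ["train"] * y.n_proteins
        idx_train = [i for i, s in enumerate(split) if s == "train"]
        idx_valid = [i for i, s in enumerate(split) if s == "valid"]
        if not idx_train:
            raise ValueError("empty training split")
        train_tokens = [by_id[y.protein_ids[i]] for i in idx_train]
        train_truth = y.truth[idx_train]
        self._build(y.n_terms)
        self.term_ids_ = list(y.term_ids)
        rng = np.random.default_rng(self.seed + 2)

        if self.mlm_steps > 0:
            self.mlm_losses_ = mlm_pretrain(
                self.encoder_,
                train_tokens,
                steps=self.mlm_steps,
                mask_rate=self.mlm_mask_rate,
                rng=np.random.default_rng(self.seed + 3),
            )

        params = (
            [] if self.freeze_encoder else self.encoder_.parameters()
        ) + self.head_.parameters()
        opt = AdamW(params, lr=self.lr, weight_decay=self.weight_decay)
        h_cache = self._encode_frozen(train_tokens) if self.freeze_encoder else None
        n = len(train_tokens)
        steps_per_epoch = int(np.ceil(n / self.batch_size))
        total_steps = self.epochs * steps_per_epoch
        step = 0
        self.history_ = []
        best_val, best_state = -1.0, None
        valid_tokens = [by_id[y.protein_ids[i]] for i in idx_valid]
        valid_truth = y.truth[idx_valid]

        for epoch in range(self.epochs):
            if not self.freeze_encoder:
                self.encoder_.train()
            self.head_.train()
            order = rng.permutation(n)
            epoch_losses = []
            for b in range(steps_per_epoch):
                batch_idx = order[b * self.batch_size : (b + 1) * self.batch_size]
                batch = [train_tokens[i] for i in batch_idx]
                if h_cache is not None:
                    H, mask = self._padded_from_cache([h_cache[i] for i in batch_idx])
                else:
                    res, st, mask = self._batch_arrays(batch)
                    H = self.encoder_.forward(res, st)
                logits = self.head_.logits(H, mask)
                loss = _bce_with_logits(logits, train_truth[batch_idx])
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}, step {b}")
                opt.zero_grad()
                loss.backward()
                opt.set_lr(linear_warmup(step, total_steps, self.lr, self.warmup_frac))
                opt.step()
                step += 1
                epoch_losses.append(loss.item())
            record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
            if valid_tokens:
                if valid_truth.sum() == 0:
                    # degenerate split: no protein with a true term, Fmax
                    # undefined; fall back to 0 so training still completes
                    record["val_fmax"] = 0.0
                else:
                    val_scores = self._score_tokens(valid_tokens)
                    val_table = PredictionTable(
                        protein_ids=[t.id for t in valid_tokens],
                        term_ids=self.term_ids_,
                        scores=val_scores,
                        truth=valid_truth,
                    )
                    record["val_fmax"] = fmax(val_table).fmax
                if record["val_fmax"] > best_val:
                    best_val = record["val_fmax"]
                    best_state = [a.copy() for a in self._state_arrays()]
            self.history_.append(record)
        if best_state is not None:
            self._load_state_arrays(best_state)
        self.best_val_fmax_ = best_val if valid_tokens else None
        return self

    # -- frozen-encoder caching -----------------------------------------------
    def _encode_frozen(self, tokens: list[TokenizedProtein], batch_size: int = 32) -> list[np.ndarray]:
        """Per-protein encoder outputs (L_i, D) with the encoder in eval mode."""
        self.encoder_.eval()
        cache: list[np.ndarray] = []
        with no_grad():
            for b in range(0, len(tokens), batch_size):
                batch = tokens[b : b + batch_size]
                res, st, _ = self._batch_arrays(batch)
                H = self.encoder_.forward(res, st).data
                cache.extend(H[i, : len(t)] for i, t in enumerate(batch))
        return cache

    def _padded_from_cache(self, rows: list[np.ndarray]) -> tuple[Tensor, np.ndarray]:
        L = max(r.shape[0] for r in rows)
        H = np.zeros((len(rows), L, rows[0].shape[1]))
        mask = np.zeros((len(rows), L))
        for i, r in enumerate(rows):
            H[i, : r.shape[0]] = r
            mask[i, : r.shape[0]] = 1.0
        return Tensor(H), mask

    # -- inference ------------------------------------------------------------
    def _score_tokens(self, tokens: list[TokenizedProtein], batch_size: int = 32) -> np.ndarray:
        self.encoder_.eval()
        self.head_.eval()
        out = []
        with no_grad():
            for b in range(0, len(tokens), batch_size):
                batch = tokens[b : b + batch_size]
                res, st, mask = self._batch_arrays(batch)
                H = self.encoder_.forward(res, st)
                out.append(self.head_(H, mask).data)
        return np.concatenate(out, axis=0)

    def predict_proba(self, X: list[TokenizedProtein]) -> np.ndarray:
        """Per-task scores in (0, 1), shape (len(X), n_tasks)."""
        if not hasattr(self, "encoder_"):
            raise RuntimeError("classifier is not fitted")
        return self._score_tokens(X)

    def predict(self, X: list[TokenizedProtein]) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int64)

    def predict_table(self, X: list[TokenizedProtein], truth: LabelTable) -> PredictionTable:
        order = {p: i for i, p in enumerate(truth.protein_ids)}
        scores = self.predict_proba(X)
        return PredictionTable(
            protein_ids=[t.id for t in X],
            term_ids=list(truth.term_ids),
            scores=scores,
            truth=truth.truth[[order[t.id] for t in X]],
        )

    # -- checkpointing --------------------------------------------------------
    def _state_arrays(self) -> list[np.ndarray]:
        return self.encoder_.state_arrays() + self.head_.state_arrays()

    def _load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        n_enc = len(self.encoder_.state_arrays())
        self.encoder_.load_state_arrays(arrays[:n_enc])
        self.head_.load_state_arrays(arrays[n_enc:])

    def save(self, path: str | Path) -> None:
        """Write a single-file checkpoint (parameters + config + history)."""
        arrays = {f"arr_{i:04d}": a for i, a in enumerate(self._state_arrays())}
        meta = {
            "params": self.get_params(),
            "n_tasks": self.n_tasks_,
            "term_ids": self.term_ids_,
            "history": getattr(self, "history_", []),
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SequenceStructureClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            arrays = [data[k] for k in sorted(data.files) if k.startswith("arr_")]
        params = meta["params"]
        params["kernel_sizes"] = tuple(params["kernel_sizes"])
        clf = cls(**params)
        clf._build(meta["n_tasks"])
        clf.term_ids_ = meta["term_ids"]
        clf.history_ = meta["history"]
        clf._load_state_arrays(arrays)
        clf.encoder_.eval()
        clf.head_.eval()
        return clf
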