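"""Multi-scale residual integration head over encoder representations.

Parallel 1-D convolutional branches of kernel widths 3, 5 and 7 run along the
sequence axis; each branch applies Conv -> BatchNorm -> GELU -> Conv ->
BatchNorm, the branch outputs are summed with an identity shortcut, blocks
are stacked, and a masked average pooling over valid residues feeds a linear
multi-label classifier with per-task logistic outputs.

Ablation modes: ``single_kernel:k`` keeps only the width-k branch;
``embedding_only`` skips the convolutional blocks entirely and pools the
encoder output straight into the linear classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv1d, MaskedBatchNorm, Linear, Module, Tensor

__all__ = ["HeadConfig", "ConvBranch", "MultiScaleBlock", "MultiScaleHead", "ABLATION_MODES"]

DEFAULT_KERNELS = (3, 5, 7)

ABLATION_MODES = ("full", "single_kernel", "embedding_only")


@dataclass
class HeadConfig:
    d_model: int = 32
    n_tasks: int = 1
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNELS
    depth: int = 2
    ablation_mode: str = "full"

    def __post_init__(self):
        base = self.ablation_mode.split(":")[0]
        if base not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {self.ablation_mode!r}")
        if base == "single_kernel":
            k = int(self.ablation_mode.split(":")[1])
            self.kernel_sizes = (k,)
        if base != "embedding_only":
            if any(k % 2 == 0 or k < 1 for k in self.kernel_sizes):
                raise ValueError("kernel sizes must be odd positive integers")
            if self.depth < 1:
                raise ValueError("depth must be >= 1")

    @property
    def embedding_only(self) -> bool:
        return self.ablation_mode == "embedding_only"


class ConvBranch(Module):
    """Conv -> BN -> GELU -> Conv -> BN at one kernel width."""

    def __init__(self, d: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(d, d, kernel_size, rng)
        self.bn1 = MaskedBatchNorm(d)
        self.conv2 = Conv1d(d, d, kernel_size, rng)
        self.bn2 = MaskedBatchNorm(d)

    def __call__(self, H: Tensor, mask: np.ndarray) -> Tensor:
        h1 = self.bn1(self.conv1(H), mask).gelu()
        return self.bn2(self.conv2(h1), mask)


class MultiScaleBlock(Module):
    """Parallel kernel branches summed with an identity shortcut."""

    def __init__(self, config: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.branches = [ConvBranch(config.d_model, k, rng) for k in config.kernel_sizes]

    def __call__(self, H: Tensor, mask: np.ndarray) -> Tensor:
        out = H
        for branch in self.branches:
            out = out + branch(H, mask)
        return out


class MultiScaleHead(Module):
    """Stacked multi-scale blocks, masked average pooling, linear classifier."""

    def __init__(self, config: HeadConfig, rng: np.random.Generator | int = 0):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        self.blocks = (
            []
            if config.embedding_only
            else [MultiScaleBlock(config, rng) for _ in range(config.depth)]
        )
        self.classifier = Linear(config.d_model, config.n_tasks, rng)

    def pool(self, H: Tensor, mask: np.ndarray) -> Tensor:
        """Mean of H over valid residues only."""
        mask = np.asarray(mask, dtype=np.float64)
        counts = mask.sum(axis=1)
        if (counts == 0).any():
            raise ValueError("cannot pool a fully padded protein")
        m = Tensor(mask[:, :, None])
        return (H * m).sum(axis=1) * Tensor(1.0 / counts[:, None])

    def logits(self, H: Tensor, mask: np.ndarray) -> Tensor:
        mask = np.asarray(mask, dtype=np.float64)
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("cannot pool a fully padded protein")
        H = H * Tensor(mask[:, :, None])
        for block in self.blocks:
            H = block(H, mask)
        return self.classifier(self.pool(H, mask))

    def __call__(self, H: Tensor, mask: np.ndarray) -> Tensor:
        """Per-task scores in (0, 1)."""
        return self.logits(H, mask).sigmoid()
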