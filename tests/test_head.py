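"""Tests for the multi-scale residual head: residual identity, conv oracle,
masked pooling, ablation consistency."""

import numpy as np
import pytest
from scipy.special import erf

from structok.head import ConvBranch, HeadConfig, MultiScaleBlock, MultiScaleHead
from structok.nn import Tensor


def _zero_branches(module):
    """Zero every convolution weight/bias in the module's branches."""
    for m in module.modules():
        if hasattr(m, "weight") and getattr(m, "kernel_size", None):
            m.weight.data[:] = 0.0
            if m.bias is not None:
                m.bias.data[:] = 0.0


def _gelu(x):
    return x * 0.5 * (1 + erf(x / np.sqrt(2)))


class TestConvBranch:
    def test_zero_weights_propagate_zero(self, rng):
        branch = ConvBranch(4, 3, rng)
        _zero_branches(branch)
        H = Tensor(rng.normal(size=(2, 6, 4)))
        mask = np.ones((2, 6))
        assert np.all(branch(H, mask).data == 0.0)

    def test_kernel_one_identity_conv_is_pure_gelu(self, rng):
        """kernel 1 with identity weights and frozen unit BN reduces the
        first stage to an elementwise GELU, checked against the erf formula."""
        branch = ConvBranch(1, 1, rng)
        branch.conv1.weight.data[:] = 1.0
        branch.conv1.bias.data[:] = 0.0
        branch.conv2.weight.data[:] = 1.0
        branch.conv2.bias.data[:] = 0.0
        for bn in (branch.bn1, branch.bn2):
            bn.eval()
            bn.running_mean[:] = 0.0
            bn.running_var[:] = 1.0 - bn.eps  # normalization becomes identity
        branch.training = False
        x = np.linspace(-3, 3, 8).reshape(1, 8, 1)
        out = branch(Tensor(x), np.ones((1, 8)))
        np.testing.assert_allclose(out.data, _gelu(x), atol=1e-12)

    def test_hand_computed_correlation(self, rng):
        """B=1, L=4, D=1, kernel 3, frozen-identity BN: the first conv equals
        a pencil-and-paper 1-D correlation with zero padding."""
        branch = ConvBranch(1, 3, rng)
        w = np.array([0.5, 1.0, -2.0])  # taps at offsets -1, 0, +1
        branch.conv1.weight.data = w.reshape(3, 1, 1)
        branch.conv1.bias.data[:] = 0.0
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expected = np.array(
            [
                w[1] * x[0] + w[2] * x[1],  # left edge: zero pad
                w[0] * x[0] + w[1] * x[1] + w[2] * x[2],
                w[0] * x[1] + w[1] * x[2] + w[2] * x[3],
                w[0] * x[2] + w[1] * x[3],  # right edge: zero pad
            ]
        )
        got = branch.conv1(Tensor(x.reshape(1, 4, 1))).data[0, :, 0]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            ConvBranch(4, 2, rng)


class TestMultiScaleBlock:
    def test_zeroed_branches_make_exact_identity(self, rng):
        config = HeadConfig(d_model=5, n_tasks=1, depth=1)
        block = MultiScaleBlock(config, rng)
        _zero_branches(block)
        H = Tensor(rng.normal(size=(2, 7, 5)))
        out = block(H, np.ones((2, 7)))
        np.testing.assert_array_equal(out.data, H.data)

    def test_default_block_has_three_parallel_branches(self, rng):
        block = MultiScaleBlock(HeadConfig(d_model=4, n_tasks=1), rng)
        assert len(block.branches) == 3
        assert [b.conv1.kernel_size for b in block.branches] == [3, 5, 7]

    def test_block_equals_sum_of_branch_outputs(self, rng):
        config = HeadConfig(d_model=4, n_tasks=1)
        block = MultiScaleBlock(config, rng)
        block.eval()
        H = Tensor(rng.normal(size=(1, 9, 4)))
        mask = np.ones((1, 9))
        expected = H.data + sum(b(H, mask).data for b in block.branches)
        np.testing.assert_allclose(block(H, mask).data, expected, atol=1e-12)


class TestPoolAndClassify:
    def test_constant_rows_pool_to_the_constant(self, rng):
        head = MultiScaleHead(HeadConfig(d_model=3, n_tasks=2), rng)
        c = np.array([1.0, -1.0, 2.5])
        H = Tensor(np.tile(c, (1, 6, 1)))
        np.testing.assert_allclose(head.pool(H, np.ones((1, 6))).data[0], c, atol=1e-12)

    def test_zero_classifier_scores_half(self, rng):
        head = MultiScaleHead(HeadConfig(d_model=3, n_tasks=4, ablation_mode="embedding_only"), rng)
        head.classifier.weight.data[:] = 0.0
        head.classifier.bias.data[:] = 0.0
        H = Tensor(rng.normal(size=(2, 5, 3)))
        np.testing.assert_allclose(head(H, np.ones((2, 5))).data, 0.5, atol=1e-12)

    def test_padding_amount_does_not_change_scores(self, rng):
        head = MultiScaleHead(HeadConfig(d_model=4, n_tasks=2), rng).eval()
        content = rng.normal(size=(4, 4))
        H1 = np.zeros((1, 6, 4))
        H1[0, :4] = content
        m1 = np.array([[1, 1, 1, 1, 0, 0]], dtype=float)
        H2 = np.zeros((1, 10, 4))
        H2[0, :4] = content
        m2 = np.array([[1, 1, 1, 1, 0, 0, 0, 0, 0, 0]], dtype=float)
        np.testing.assert_allclose(
            head(Tensor(H1), m1).data, head(Tensor(H2), m2).data, atol=1e-5
        )

    def test_fully_padded_protein_rejected(self, rng):
        head = MultiScaleHead(HeadConfig(d_model=3, n_tasks=1), rng)
        with pytest.raises(ValueError):
            head(Tensor(np.zeros((1, 4, 3))), np.zeros((1, 4)))


class TestAblations:
    def test_embedding_only_matches_two_line_arithmetic(self, rng):
        head = MultiScaleHead(HeadConfig(d_model=2, n_tasks=1, ablation_mode="embedding_only"), rng)
        head.classifier.weight.data = np.array([[0.5], [-1.0]])
        head.classifier.bias.data = np.array([0.25])
        c = np.array([2.0, 1.0])
        H = Tensor(np.tile(c, (1, 5, 1)))
        logit = 0.5 * 2.0 - 1.0 * 1.0 + 0.25
        np.testing.assert_allclose(
            head(H, np.ones((1, 5))).data[0, 0], 1 / (1 + np.exp(-logit)), atol=1e-12
        )

    def test_single_kernel_mode_equals_full_with_one_kernel(self):
        cfg_a = HeadConfig(d_model=4, n_tasks=2, ablation_mode="single_kernel:3")
        cfg_b = HeadConfig(d_model=4, n_tasks=2, kernel_sizes=(3,), ablation_mode="full")
        head_a = MultiScaleHead(cfg_a, np.random.default_rng(5))
        head_b = MultiScaleHead(cfg_b, np.random.default_rng(5))
        rng = np.random.default_rng(0)
        H = rng.normal(size=(2, 6, 4))
        mask = np.ones((2, 6))
        head_a.eval(), head_b.eval()
        np.testing.assert_array_equal(
            head_a(Tensor(H), mask).data, head_b(Tensor(H), mask).data
        )

    def test_deep_zeroed_blocks_match_embedding_only_path(self, rng):
        cfg = HeadConfig(d_model=3, n_tasks=2, depth=2)
        head = MultiScaleHead(cfg, np.random.default_rng(9))
        _zero_branches(head)
        H = Tensor(rng.normal(size=(2, 5, 3)))
        mask = np.ones((2, 5))
        expected = head.classifier(head.pool(H, mask)).sigmoid().data
        np.testing.assert_allclose(head(H, mask).data, expected, atol=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            HeadConfig(d_model=4, n_tasks=1, ablation_mode="half_kernels")
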