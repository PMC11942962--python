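"""Tests for disentangled attention: term structure, oracles, nullification."""

import numpy as np
import pytest
from scipy.special import erf

from structok.core import RESIDUE_MASK, RESIDUE_PAD, TokenizedProtein
from structok.encoder import (
    ALL_INTERACTIONS,
    RETAINED_INTERACTIONS,
    EncoderConfig,
    SSTEncoder,
    mlm_pretrain,
    pad_token_batch,
    relative_index_matrix,
    relative_position_index,
)
from structok.nn import Tensor


def _config(**kw):
    defaults = dict(d_model=8, n_heads=2, n_layers=1, n_structure_vocab=6, r_max=4, ff_dim=12)
    defaults.update(kw)
    return EncoderConfig(**defaults)


def _tokens(L, rng, K=6):
    return (
        rng.integers(0, 21, size=(1, L)),
        rng.integers(0, K, size=(1, L)),
    )


class TestRelativePositions:
    def test_zero_offset_maps_to_center_slot(self):
        assert relative_position_index(3, 3, r_max=8) == 8

    def test_direct_formula_example(self):
        assert relative_position_index(0, 3, r_max=8) == 11

    def test_antisymmetric_before_clipping(self):
        for i, j in [(0, 3), (5, 1), (2, 2)]:
            d_ij = relative_position_index(i, j, 100) - 100
            d_ji = relative_position_index(j, i, 100) - 100
            assert d_ij == -d_ji

    def test_matrix_matches_double_loop(self):
        L, r = 10, 2
        mat = relative_index_matrix(L, r)
        for i in range(L):
            for j in range(L):
                assert mat[i, j] == min(max(j - i, -r), r) + r


class TestInteractionDecomposition:
    def test_full_factorization_has_nine_components(self):
        assert len(ALL_INTERACTIONS) == 9

    def test_implemented_score_retains_five_types(self):
        assert len(RETAINED_INTERACTIONS) == 5
        removed = set(ALL_INTERACTIONS) - set(RETAINED_INTERACTIONS)
        assert removed == {
            ("structure", "structure"),
            ("structure", "position"),
            ("position", "structure"),
            ("position", "position"),
        }


def _five_term_oracle(S, ST, P, attn, cfg):
    """Independent score computation: explicit loops over heads and pairs."""
    L = S.shape[1]
    H, dh = cfg.n_heads, cfg.d_head
    Qs = S[0] @ attn.Wq_s.weight.data
    Ks = S[0] @ attn.Wk_s.weight.data
    Qst = ST[0] @ attn.Wq_st.weight.data
    Kst = ST[0] @ attn.Wk_st.weight.data
    Qp = P @ attn.Wq_p.weight.data
    Kp = P @ attn.Wk_p.weight.data
    out = np.zeros((1, H, L, L))
    for h in range(H):
        sl = slice(h * dh, (h + 1) * dh)
        for i in range(L):
            for j in range(L):
                dij = min(max(j - i, -cfg.r_max), cfg.r_max) + cfg.r_max
                dji = min(max(i - j, -cfg.r_max), cfg.r_max) + cfg.r_max
                out[0, h, i, j] = (
                    Qs[i, sl] @ Ks[j, sl]
                    + Qs[i, sl] @ Kst[j, sl]
                    + Qs[i, sl] @ Kp[dij, sl]
                    + Qst[i, sl] @ Ks[j, sl]
                    + Qp[dji, sl] @ Ks[j, sl]
                )
    return out


class TestAttentionScores:
    @pytest.mark.parametrize("L", [2, 4, 6])
    def test_scores_equal_term_by_term_oracle(self, L, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=1)
        res, st = _tokens(L, rng)
        S, ST, P, _ = model.embed_inputs(res, st)
        attn = model.layers[0].attn
        got = attn.scores(S, ST, P).data
        expected = _five_term_oracle(S.data, ST.data, P.data, attn, cfg)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_zero_structure_and_position_leave_pure_content_score(self, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=2)
        model.structure_embedding.weight.data[:] = 0.0
        model.position_embedding.data[:] = 0.0
        res, st = _tokens(5, rng)
        S, ST, P, _ = model.embed_inputs(res, st)
        attn = model.layers[0].attn
        got = attn.scores(S, ST, P).data
        Qs = S.data[0] @ attn.Wq_s.weight.data
        Ks = S.data[0] @ attn.Wk_s.weight.data
        for h in range(cfg.n_heads):
            sl = slice(h * cfg.d_head, (h + 1) * cfg.d_head)
            np.testing.assert_allclose(got[0, h], Qs[:, sl] @ Ks[:, sl].T, atol=1e-12)


class TestAttentionOutput:
    def test_uniform_scores_average_unmasked_values(self, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=3)
        attn = model.layers[0].attn
        L = 4
        res, st = _tokens(L, rng)
        S, ST, P, _ = model.embed_inputs(res, st)
        # identical tokens at every position -> identical rows -> uniform rows
        res_u = np.full((1, L), 7)
        st_u = np.full((1, L), 2)
        S, ST, P, mask = model.embed_inputs(res_u, st_u)
        out = attn(S, ST, P, mask)
        Vs = S.data[0] @ attn.Wv_s.weight.data
        expected = np.tile(Vs.mean(axis=0), (L, 1)) @ attn.out_proj.weight.data + attn.out_proj.bias.data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-10)

    def test_masked_key_gets_zero_attention_weight(self, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=4)
        attn = model.layers[0].attn
        L = 5
        res, st = _tokens(L, rng)
        S, ST, P, mask = model.embed_inputs(res, st)
        mask[0, 3] = 0.0
        raw = attn.scores(S, ST, P)
        scaled = raw * (1.0 / np.sqrt(5.0 * cfg.d_head))
        bias = Tensor((1.0 - mask)[:, None, None, :] * -1e9)
        weights = (scaled + bias).softmax(axis=-1).data
        assert np.all(weights[..., 3] == 0.0)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_scaling_uses_sqrt_5d(self, rng):
        """softmax(A / sqrt(5 d)) against a hand-coded softmax on one row."""
        cfg = _config(d_model=8, n_heads=2)  # d_head = 4 -> scale sqrt(20)
        model = SSTEncoder(cfg, seed=5)
        attn = model.layers[0].attn
        res, st = _tokens(3, rng)
        S, ST, P, mask = model.embed_inputs(res, st)
        raw = attn.scores(S, ST, P).data
        scaled = (raw / np.sqrt(20.0))[0, 0]
        expected = np.exp(scaled - scaled.max(axis=-1, keepdims=True))
        expected /= expected.sum(axis=-1, keepdims=True)
        got = (attn.scores(S, ST, P) * (1.0 / np.sqrt(5.0 * cfg.d_head))).softmax(axis=-1).data
        np.testing.assert_allclose(got[0, 0], expected, atol=1e-9)

    def test_fully_masked_sequence_rejected(self, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=6)
        res = np.full((1, 3), RESIDUE_PAD)
        st = np.full((1, 3), cfg.structure_pad)
        S, ST, P, mask = model.embed_inputs(res, st)
        with pytest.raises(ValueError):
            model.layers[0].attn(S, ST, P, mask)


def _vanilla_transformer_reference(model, res):
    """Independent numpy implementation of a content-only pre-LN transformer
    reusing the model's weights (structure/position contributions zeroed)."""
    cfg = model.config

    def ln(x, g, b):
        mu = x.mean(-1, keepdims=True)
        v = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(v + 1e-5) * g + b

    def gelu(x):
        return x * 0.5 * (1 + erf(x / np.sqrt(2)))

    x = model.residue_embedding.weight.data[res[0]]
    H, dh = cfg.n_heads, cfg.d_head
    for layer in model.layers:
        a = layer.attn
        xin = ln(x, layer.norm1.gamma.data, layer.norm1.beta.data)
        Q = xin @ a.Wq_s.weight.data
        K = xin @ a.Wk_s.weight.data
        V = xin @ a.Wv_s.weight.data
        heads = []
        for h in range(H):
            sl = slice(h * dh, (h + 1) * dh)
            sc = Q[:, sl] @ K[:, sl].T / np.sqrt(5.0 * dh)
            w = np.exp(sc - sc.max(-1, keepdims=True))
            w /= w.sum(-1, keepdims=True)
            heads.append(w @ V[:, sl])
        att = np.concatenate(heads, axis=-1) @ a.out_proj.weight.data + a.out_proj.bias.data
        x = x + att
        xin = ln(x, layer.norm2.gamma.data, layer.norm2.beta.data)
        ff = gelu(xin @ layer.ff1.weight.data + layer.ff1.bias.data)
        x = x + ff @ layer.ff2.weight.data + layer.ff2.bias.data
    return ln(x, model.final_norm.gamma.data, model.final_norm.beta.data)


class TestEncoderForward:
    def test_single_residue_protein(self, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=7).eval()
        out = model.forward(np.array([[4]]), np.array([[1]]))
        assert out.shape == (1, 1, cfg.d_model)

    def test_eval_mode_bitwise_deterministic(self, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=8).eval()
        res, st = _tokens(6, rng)
        np.testing.assert_array_equal(model.forward(res, st).data, model.forward(res, st).data)

    def test_padding_does_not_change_valid_positions(self, rng):
        cfg = _config(n_layers=2)
        model = SSTEncoder(cfg, seed=9).eval()
        L = 6
        res, st = _tokens(L, rng)
        out = model.forward(res, st).data
        res_p = np.concatenate([res, np.full((1, 8), RESIDUE_PAD)], axis=1)
        st_p = np.concatenate([st, np.full((1, 8), cfg.structure_pad)], axis=1)
        out_p = model.forward(res_p, st_p).data
        np.testing.assert_allclose(out_p[:, :L], out, atol=1e-5)
        assert np.all(out_p[:, L:] == 0.0)

    def test_nullification_collapses_to_vanilla_transformer(self, rng):
        """With structure and position embeddings zeroed, the encoder equals
        an independently coded content-only transformer with the same
        weights."""
        cfg = _config(n_layers=2, d_model=12, n_heads=3, ff_dim=16)
        model = SSTEncoder(cfg, seed=10).eval()
        model.structure_embedding.weight.data[:] = 0.0
        model.position_embedding.data[:] = 0.0
        res, st = _tokens(6, rng)
        got = model.forward(res, st).data[0]
        expected = _vanilla_transformer_reference(model, res)
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_shuffled_structure_tokens_change_output(self, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=11).eval()
        res = rng.integers(0, 21, size=(1, 8))
        st = np.arange(8)[None] % cfg.n_structure_vocab
        out1 = model.forward(res, st).data
        out2 = model.forward(res, st[:, ::-1]).data
        assert np.abs(out1 - out2).max() > 1e-8

    def test_out_of_vocab_rejected(self):
        cfg = _config()
        model = SSTEncoder(cfg, seed=12)
        with pytest.raises(ValueError):
            model.forward(np.array([[99]]), np.array([[0]]))


class TestMLM:
    def test_uniform_logits_give_log21_loss(self, rng):
        cfg = _config()
        model = SSTEncoder(cfg, seed=13)
        model.mlm_head.weight.data[:] = 0.0
        model.mlm_head.bias.data[:] = 0.0
        res, st = _tokens(10, rng)
        loss = model.mlm_step_loss(res, st, mask_rate=0.15, rng=np.random.default_rng(0))
        np.testing.assert_allclose(loss.item(), np.log(21.0), atol=1e-12)

    def test_structure_tokens_never_masked(self, rng):
        """Across 10 seeded corruption draws, the structure stream reaching
        the forward pass is exactly the input stream, and the mask symbol
        never appears in it."""
        cfg = _config()
        model = SSTEncoder(cfg, seed=14)
        res, st = _tokens(12, rng)
        seen_st = []
        orig_forward = model.forward

        def spy(res_ids, st_ids):
            seen_st.append(np.array(st_ids))
            return orig_forward(res_ids, st_ids)

        model.forward = spy
        for seed in range(10):
            model.mlm_step_loss(res, st, 0.3, np.random.default_rng(seed))
        for captured in seen_st:
            np.testing.assert_array_equal(captured, st)
            assert RESIDUE_MASK not in captured

    def test_pretraining_reduces_loss(self, small_proteins, fitted_tokenizer):
        tokens = fitted_tokenizer.transform(small_proteins[:10])
        cfg = _config(n_structure_vocab=fitted_tokenizer.codebook_.K)
        model = SSTEncoder(cfg, seed=15)
        losses = mlm_pretrain(
            model, tokens, steps=60, mask_rate=0.15, rng=np.random.default_rng(0)
        )
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_invalid_mask_rate_rejected(self, rng):
        model = SSTEncoder(_config(), seed=16)
        res, st = _tokens(5, rng)
        with pytest.raises(ValueError):
            model.mlm_step_loss(res, st, 0.0, np.random.default_rng(0))


def test_pad_token_batch_shapes():
    t1 = TokenizedProtein(id="a", residue_tokens=[1, 2, 3], structure_tokens=[0, 1, 0])
    t2 = TokenizedProtein(id="b", residue_tokens=[4], structure_tokens=[2])
    res, st = pad_token_batch([t1, t2], structure_pad=9)
    assert res.shape == (2, 3)
    assert res[1, 1] == RESIDUE_PAD and st[1, 1] == 9
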