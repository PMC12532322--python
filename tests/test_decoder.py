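"""Attention mechanics, distance mask, and decoder losses."""

import numpy as np
import pytest

from attune.data_model import GeneAnnotation, PeakInterval
from attune.decoder import (AttentionMask, DecoderParams, GlobalAttentionMatrix,
                            _cls_row_self, build_attention_mask,
                            cls_contrastive_loss, cross_attention,
                            extract_global_attention, interaction_loss,
                            matching_loss, prepend_cls, self_attention)
from attune.encoders import TokenHidden
from attune.pretrain import nt_xent_cross_modal
from attune._autodiff import Tensor


@pytest.fixture
def params():
    return DecoderParams(d=4, seed=0)


def brute_force_attention(q, k, v, scale, mask=None):
    """Direct-sum attention oracle."""
    out = np.empty_like(q)
    w = np.empty((q.shape[0], q.shape[1], k.shape[1]))
    for n in range(q.shape[0]):
        for i in range(q.shape[1]):
            logits = np.array([q[n, i] @ k[n, j] for j in range(k.shape[1])])
            if mask is not None:
                logits = logits + mask[i]
            logits = logits * scale
            e = np.exp(logits - logits.max())
            w[n, i] = e / e.sum()
            out[n, i] = sum(w[n, i, j] * v[n, j] for j in range(k.shape[1]))
    return out, w


class TestPrependCls:
    def test_cls_at_slot_zero_order_preserved(self):
        tokens = TokenHidden(np.arange(24, dtype=float).reshape(2, 3, 4), "RNA")
        cls = np.full(4, 7.0)
        out = prepend_cls(tokens, cls)
        assert out.values.shape == (2, 4, 4)
        assert np.allclose(out.values[:, 0], 7.0)
        assert np.array_equal(out.values[:, 1:], tokens.values)

    def test_strip_recovers_input(self):
        tokens = TokenHidden(np.random.default_rng(0).normal(size=(2, 3, 4)), "RNA")
        out = prepend_cls(tokens, np.zeros(4))
        assert np.array_equal(out.values[:, 1:], tokens.values)


class TestSelfAttention:
    def test_rows_sum_to_one(self, params):
        rng = np.random.default_rng(1)
        tokens = rng.normal(size=(2, 5, 4))
        _, w = self_attention(tokens, params)
        assert np.allclose(w.sum(axis=-1), 1.0)

    def test_single_token_output_is_its_value_projection(self, params):
        tokens = np.random.default_rng(2).normal(size=(1, 1, 4))
        out, w = self_attention(tokens, params)
        assert np.allclose(w, 1.0)
        assert np.allclose(out[0, 0], tokens[0, 0] @ params.Wv_self.data)

    def test_matches_brute_force_oracle(self, params):
        rng = np.random.default_rng(3)
        tokens = rng.normal(size=(2, 3, 4))
        out, w = self_attention(tokens, params)
        q = tokens @ params.Wq_self.data
        k = tokens @ params.Wk_self.data
        v = tokens @ params.Wv_self.data
        ref_out, ref_w = brute_force_attention(q, k, v, 1 / 2.0)
        assert np.allclose(out, ref_out, atol=1e-6)
        assert np.allclose(w, ref_w, atol=1e-6)

    def test_cls_row_shortcut_equals_full_row_zero(self, params):
        rng = np.random.default_rng(4)
        tokens = rng.normal(size=(3, 6, 4))
        full_out, full_w = self_attention(tokens, params)
        cls_out, cls_w = _cls_row_self(Tensor(tokens), params)
        assert np.allclose(cls_out.data[:, 0], full_out[:, 0], atol=1e-10)
        assert np.allclose(cls_w[:, 0], full_w[:, 0], atol=1e-10)

    def test_factored_cls_paths_equal_materialized_attention(self, params):
        """Count-scaled token attention computed by the factored path
        matches the materialized token-stack computation exactly."""
        from attune.decoder import (_factored_cls_cross, _factored_cls_self,
                                    prepend_cls)
        from attune.encoders import TokenHidden

        rng = np.random.default_rng(20)
        b, f, d = 3, 7, 4
        x = rng.poisson(1.0, size=(b, f)).astype(float)
        e_table = rng.normal(size=(f, d))
        cls_vec = rng.normal(size=d)
        tokens = prepend_cls(TokenHidden(x[:, :, None] * e_table[None], "RNA"),
                             cls_vec).values

        full_out, full_w = self_attention(tokens, params)
        fac_out, fac_w = _factored_cls_self(x, Tensor(e_table),
                                            Tensor(cls_vec), params)
        assert np.allclose(fac_out.data, full_out[:, 0], atol=1e-10)
        assert np.allclose(fac_w.data, full_w[:, 0], atol=1e-10)

        # cross: queries = the factored CLS outputs; keys/values = a second
        # count-scaled token set with its own CLS
        x2 = rng.poisson(1.0, size=(b, 5)).astype(float)
        e2 = rng.normal(size=(5, d))
        cls2 = rng.normal(size=d)
        kv_tokens = prepend_cls(TokenHidden(x2[:, :, None] * e2[None], "ATAC"),
                                cls2).values
        mask = AttentionMask(np.zeros((1, 6)))
        out_m, w_m = cross_attention(fac_out.data[:, None, :], kv_tokens,
                                     mask, params)
        out_f, w_f = _factored_cls_cross(fac_out, x2, Tensor(e2),
                                         Tensor(cls2), params)
        assert np.allclose(out_f.data, out_m[:, 0], atol=1e-10)
        assert np.allclose(w_f.data, w_m[:, 0], atol=1e-10)


class TestAttentionMask:
    GENES = [GeneAnnotation("g1", "g1", "chr1", 1_000_000, "+"),
             GeneAnnotation("g2", "g2", "chr2", 1_000_000, "+")]
    PEAKS = [PeakInterval("chr1", 2_299_750, 2_300_250),   # mid 2.3 Mb -> masked
             PeakInterval("chr1", 999_900, 1_000_100),     # overlaps TSS -> open
             PeakInterval("chr1", 2_199_750, 2_200_250)]   # exactly 1.2 Mb -> open

    def test_distance_threshold(self):
        mask = build_attention_mask(self.GENES, self.PEAKS)
        assert mask.values[1, 1] < 0            # 1.3 Mb > 1.2 Mb
        assert mask.values[1, 2] == 0           # distance 0
        assert mask.values[1, 3] == 0           # exactly at threshold: inclusive

    def test_cross_chromosome_always_masked(self):
        mask = build_attention_mask(self.GENES, self.PEAKS)
        assert np.all(mask.values[2, 1:] < 0)

    def test_cls_row_and_column_unmasked(self):
        mask = build_attention_mask(self.GENES, self.PEAKS)
        assert np.all(mask.values[0, :] == 0)
        assert np.all(mask.values[:, 0] == 0)


class TestCrossAttention:
    def _setup(self, params, rng, g=2, p=3):
        gene_tokens = rng.normal(size=(2, g + 1, 4))
        peak_tokens = rng.normal(size=(2, p + 1, 4))
        values = np.zeros((g + 1, p + 1))
        values[1, 2] = -1e9
        return gene_tokens, peak_tokens, AttentionMask(values)

    def test_unmasked_rows_sum_to_one_and_masked_tiny(self, params):
        rng = np.random.default_rng(5)
        gt, pt, mask = self._setup(params, rng)
        _, w = cross_attention(gt, pt, mask, params)
        assert np.allclose(w.sum(axis=-1), 1.0)
        assert np.all(w[:, 1, 2] <= 1e-6)

    def test_fully_masked_gene_row_attends_cls_only(self, params):
        rng = np.random.default_rng(6)
        gt, pt, mask = self._setup(params, rng)
        mask.values[2, 1:] = -1e9               # gene 2: every peak masked
        _, w = cross_attention(gt, pt, mask, params)
        assert np.allclose(w[:, 2, 0], 1.0, atol=1e-6)

    def test_matches_brute_force_oracle(self, params):
        rng = np.random.default_rng(7)
        gt, pt, mask = self._setup(params, rng)
        out, w = cross_attention(gt, pt, mask, params)
        q = gt @ params.Wq_cross.data
        k = pt @ params.Wk_cross.data
        v = pt @ params.Wv_cross.data
        ref_out, ref_w = brute_force_attention(q, k, v, 1 / 2.0, mask=mask.values)
        assert np.allclose(out, ref_out, atol=1e-6)
        assert np.allclose(w, ref_w, atol=1e-6)

    def test_masked_peak_perturbation_does_not_change_output(self, params):
        rng = np.random.default_rng(8)
        gt, pt, mask = self._setup(params, rng)
        out1, _ = cross_attention(gt, pt, mask, params)
        pt2 = pt.copy()
        pt2[:, 2, :] += 100.0                   # peak 2 is masked for gene 1
        out2, _ = cross_attention(gt, pt2, mask, params)
        assert np.allclose(out1[:, 1], out2[:, 1], atol=1e-4)


class TestLosses:
    def test_cls_contrastive_shares_nt_xent_engine(self):
        rng = np.random.default_rng(9)
        g, p = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        assert cls_contrastive_loss(g, p, 0.1) == pytest.approx(
            nt_xent_cross_modal(g, p, 0.1))

    def test_cls_identical_single_pair_log_two(self):
        v = np.array([[1.0, 0.0]])
        assert cls_contrastive_loss(v, v, 0.1) == pytest.approx(np.log(2.0))

    def test_uniform_classifier_matching_loss_is_log_two(self, params):
        # zero classifier weights -> logits (0, 0) -> p = (0.5, 0.5)
        params.Wc.data[...] = 0.0
        params.bc.data[...] = 0.0
        rng = np.random.default_rng(10)
        gt = rng.normal(size=(3, 4, 4))
        pt = rng.normal(size=(3, 5, 4))
        sims = rng.normal(size=(3, 3))
        loss = matching_loss(gt, pt, sims, params, np.random.default_rng(0))
        assert loss == pytest.approx(np.log(2.0))

    def test_matching_loss_matches_independent_numpy_forward(self, params):
        rng = np.random.default_rng(11)
        gt = rng.normal(size=(2, 3, 4))         # already self-attended, CLS at 0
        pt = rng.normal(size=(2, 4, 4))
        sims = rng.normal(size=(2, 2))
        loss, info = matching_loss(gt, pt, sims, params,
                                   np.random.default_rng(1), return_details=True)
        # independent recomputation in plain numpy
        def cls_cross(kv):
            q = gt[:, :1, :] @ params.Wq_cross.data
            k = kv @ params.Wk_cross.data
            v = kv @ params.Wv_cross.data
            out, _ = brute_force_attention(q, k, v, 1 / 2.0)
            return out[:, 0, :]
        pos = cls_cross(pt)
        neg = cls_cross(pt[info["negatives"]])
        logits = np.vstack([pos, neg]) @ params.Wc.data + params.bc.data
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        want = -np.mean(np.log(probs[np.arange(4), info["labels"]]))
        assert loss == pytest.approx(want, rel=1e-8)

    def test_negatives_never_self(self, params):
        rng = np.random.default_rng(12)
        sims = rng.normal(size=(6, 6))
        _, info = matching_loss(rng.normal(size=(6, 2, 4)),
                                rng.normal(size=(6, 3, 4)), sims, params,
                                np.random.default_rng(2), return_details=True)
        assert np.all(info["negatives"] != np.arange(6))

    def test_interaction_loss_is_commutative_sum(self):
        assert interaction_loss(1.5, 2.5) == 4.0
        assert interaction_loss(0.0, 0.0) == 0.0
        assert interaction_loss(2.5, 1.5) == interaction_loss(1.5, 2.5)


class TestGlobalAttention:
    def test_uniform_rows_give_constant_matrix(self):
        n, g, p = 1, 3, 4
        cls_rna = np.full((n, p + 1), 1.0 / (p + 1))
        cls_atac = np.full((n, g + 1), 1.0 / (g + 1))
        out = extract_global_attention(cls_rna, cls_atac,
                                       [f"g{i}" for i in range(g)],
                                       [f"p{i}" for i in range(p)])
        assert out.values.shape == (g, p)
        assert np.allclose(out.values, 1.0 / ((g + 1) * (p + 1)))

    def test_nonnegative_and_masked_zero(self):
        rng = np.random.default_rng(13)
        n, g, p = 5, 2, 3
        def rows(width):
            e = rng.random((n, width))
            return e / e.sum(axis=1, keepdims=True)
        values = np.zeros((g + 1, p + 1))
        values[1, 1] = -1e9
        mask = AttentionMask(values)
        out = extract_global_attention(rows(p + 1), rows(g + 1),
                                       ["ga", "gb"], ["pa", "pb", "pc"], mask=mask)
        assert np.all(out.values >= 0)
        assert out.values[0, 0] == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            extract_global_attention(np.ones((2, 4)), np.ones((3, 3)),
                                     ["g0", "g1"], ["p0", "p1", "p2"])
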