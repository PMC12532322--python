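"""Transformer decoder scoring gene-peak regulatory interactions.

Token sequences are the count-weighted gene/peak embeddings from the
pretrained teacher encoders with a learned CLS token prepended. Gene
tokens pass self-attention, then cross-attend to peak tokens under an
additive genomic-distance mask (pairs farther than ``threshold_bp`` from
the gene TSS, or on another chromosome, are masked out). Training
combines an NT-Xent contrastive loss on the two modality CLS embeddings
with a binary matching loss over true and hard-negative cell pairings.
The global gene-peak score matrix is the contraction over cells of the
two CLS attention rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, concat, softmax
from .data_model import GeneAnnotation, PeakInterval, ProcessedData
from .encoders import EncoderParams, TokenHidden
from .pretrain import _nt_xent_tensor

MASK_VALUE = -1e9
DEFAULT_THRESHOLD_BP = 1_200_000


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class AttentionMask:
    """Additive (G+1) x (P+1) mask, 0 = allowed, -1e9 = masked.

    Row/column 0 are the CLS slots and are never masked. The mask is
    shared by all cells.
    """

    values: np.ndarray
    threshold_bp: int = DEFAULT_THRESHOLD_BP

    @property
    def allowed(self) -> np.ndarray:
        """Boolean G x P matrix of unmasked gene-peak pairs (CLS dropped)."""
        return self.values[1:, 1:] == 0.0


@dataclass
class GlobalAttentionMatrix:
    """G x P nonnegative gene-peak attention scores with aligned ids."""

    values: np.ndarray
    gene_ids: list[str]
    peak_ids: list[str]
    allowed: np.ndarray | None = None

    def __post_init__(self):
        if self.values.shape != (len(self.gene_ids), len(self.peak_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if self.allowed is None:
            self.allowed = self.values > 0

    def to_pairs(self) -> pd.DataFrame:
        gi, pi = np.nonzero(self.allowed)
        return pd.DataFrame({
            "gene_id": [self.gene_ids[i] for i in gi],
            "peak_id": [self.peak_ids[j] for j in pi],
            "weight": self.values[gi, pi],
        })


@dataclass
class DecoderConfig:
    epochs: int = 5
    batch_size: int = 32
    lr: float = 1e-3
    tau_cls: float = 1.0
    heads: int = 1
    qk_gain: float = 4.0
    threshold_bp: int = DEFAULT_THRESHOLD_BP
    freeze_encoder: bool = False
    negative_mode: str = "uniform"       # uniform | low_similarity | high_similarity
    seed: int = 0


class DecoderParams:
    """CLS embeddings, shared self/cross Q-K-V projections, matching classifier.

    ``qk_gain`` scales the query/key projection init: with count-scaled
    token hiddens and d = 128, plain Glorot initialization leaves the
    attention logits nearly zero, so softmax starts uniform and the
    attention pathway receives almost no gradient; the gain calibrates
    the initial logit spread to unit order.
    """

    def __init__(self, d: int, heads: int = 1, tau_cls: float = 1.0,
                 qk_gain: float = 4.0, seed: int = 0):
        if d % heads:
            raise ValueError("embedding dim must be divisible by heads")
        rng = np.random.default_rng(seed)
        limit = np.sqrt(6.0 / (2 * d))
        def mat(gain=1.0):
            return Tensor(gain * rng.uniform(-limit, limit, size=(d, d)),
                          requires_grad=True)
        self.d, self.heads, self.tau_cls = d, heads, tau_cls
        self.qk_gain = qk_gain
        self.cls_gene = Tensor(rng.normal(0, 1 / np.sqrt(d), d), requires_grad=True)
        self.cls_peak = Tensor(rng.normal(0, 1 / np.sqrt(d), d), requires_grad=True)
        self.Wq_self, self.Wk_self, self.Wv_self = mat(qk_gain), mat(qk_gain), mat()
        self.Wq_cross, self.Wk_cross, self.Wv_cross = mat(qk_gain), mat(qk_gain), mat()
        self.Wc = Tensor(rng.uniform(-limit, limit, size=(d, 2)), requires_grad=True)
        self.bc = Tensor(np.zeros(2), requires_grad=True)

    _ARRS = ("cls_gene", "cls_peak", "Wq_self", "Wk_self", "Wv_self",
             "Wq_cross", "Wk_cross", "Wv_cross", "Wc", "bc")

    @property
    def params(self):
        return [getattr(self, name) for name in self._ARRS]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs.update({"d": self.d, "heads": self.heads,
                            "tau_cls": self.tau_cls, "qk_gain": self.qk_gain})
            for name in self._ARRS:
                f.create_dataset(name, data=getattr(self, name).data)

    @classmethod
    def load(cls, path) -> "DecoderParams":
        with h5py.File(path, "r") as f:
            out = cls(int(f.attrs["d"]), heads=int(f.attrs["heads"]),
                      tau_cls=float(f.attrs["tau_cls"]),
                      qk_gain=float(f.attrs["qk_gain"]))
            for name in cls._ARRS:
                getattr(out, name).data[...] = f[name][:]
        return out


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def build_attention_mask(genes: list[GeneAnnotation], peaks: list[PeakInterval],
                         threshold_bp: int = DEFAULT_THRESHOLD_BP) -> AttentionMask:
    """Allow a gene-peak pair iff same chromosome and |TSS - midpoint| <= threshold."""
    missing = [i for i, g in enumerate(genes) if not g.chrom] + \
              [f"peak {i}" for i, p in enumerate(peaks) if not p.chrom]
    if missing:
        raise ValueError(f"features missing chromosome annotation: {missing[:10]}")
    gene_chrom = np.array([g.chrom for g in genes])
    peak_chrom = np.array([p.chrom for p in peaks])
    tss = np.array([g.tss for g in genes])[:, None]
    mid = np.array([p.midpoint for p in peaks])[None, :]
    same = gene_chrom[:, None] == peak_chrom[None, :]
    near = np.abs(tss - mid) <= threshold_bp
    values = np.zeros((len(genes) + 1, len(peaks) + 1))
    values[1:, 1:] = np.where(same & near, 0.0, MASK_VALUE)
    return AttentionMask(values=values, threshold_bp=threshold_bp)


def prepend_cls(tokens: TokenHidden, cls_embedding: np.ndarray) -> TokenHidden:
    """Insert the CLS embedding at position 0 of every cell's token sequence."""
    vals = np.asarray(tokens.values)
    cls_tile = np.broadcast_to(cls_embedding, (vals.shape[0], 1, vals.shape[2]))
    return TokenHidden(values=np.concatenate([cls_tile, vals], axis=1),
                       modality=tokens.modality)


def _multi_head_attention(q: Tensor, k: Tensor, v: Tensor, heads: int,
                          mask2d: np.ndarray | None = None):
    """softmax((QK^T + mask)/sqrt(d_head)) V; returns (output, head-mean weights)."""
    b, tq, d = q.shape
    tk = k.shape[1]
    dh = d // heads
    qh = q.reshape(b, tq, heads, dh).swapaxes(1, 2)
    kh = k.reshape(b, tk, heads, dh).swapaxes(1, 2)
    vh = v.reshape(b, tk, heads, dh).swapaxes(1, 2)
    scores = qh @ kh.swapaxes(-1, -2)
    if mask2d is not None:
        scores = scores + Tensor(mask2d)
    scores = scores * (1.0 / np.sqrt(dh))
    weights = softmax(scores, axis=-1)                      # b, h, tq, tk
    out = (weights @ vh).swapaxes(1, 2).reshape(b, tq, d)
    return out, weights.data.mean(axis=1)


def _self_attend(tokens: Tensor, params: DecoderParams):
    q, k, v = tokens @ params.Wq_self, tokens @ params.Wk_self, tokens @ params.Wv_self
    return _multi_head_attention(q, k, v, params.heads)


def _cross_attend(queries: Tensor, keys: Tensor, params: DecoderParams,
                  mask2d: np.ndarray, kv_rows: np.ndarray | None = None):
    q = queries @ params.Wq_cross
    k = keys @ params.Wk_cross
    v = keys @ params.Wv_cross
    if kv_rows is not None:                                  # mismatched pairings
        k, v = k.take_rows(kv_rows), v.take_rows(kv_rows)
    return _multi_head_attention(q, k, v, params.heads, mask2d=mask2d)


def self_attention(tokens: np.ndarray, params: DecoderParams):
    """Self-attention over a CLS-prefixed token sequence (numpy API).

    Returns (hidden N x T x d, weights N x T x T); weight rows sum to 1.
    """
    out, w = _self_attend(Tensor(np.asarray(tokens, float)), params)
    return out.data, w


def cross_attention(self_gene_hidden: np.ndarray, peak_tokens: np.ndarray,
                    mask: AttentionMask, params: DecoderParams):
    """Distance-masked cross-attention of gene queries onto peak tokens.

    Both inputs carry the CLS slot at position 0; mask shape must match.
    """
    if mask.values.shape != (self_gene_hidden.shape[1], peak_tokens.shape[1]):
        raise ValueError("mask shape does not match token sequences")
    out, w = _cross_attend(Tensor(np.asarray(self_gene_hidden, float)),
                           Tensor(np.asarray(peak_tokens, float)), params,
                           mask2d=mask.values)
    return out.data, w


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cls_contrastive_loss(gene_cls: np.ndarray, peak_cls: np.ndarray,
                         tau: float = 0.1) -> float:
    """NT-Xent on the paired CLS embeddings (same engine as pretraining)."""
    from .pretrain import nt_xent_cross_modal
    return nt_xent_cross_modal(gene_cls, peak_cls, tau)


def sample_negatives(cls_similarities: np.ndarray, rng: np.random.Generator,
                     mode: str = "uniform") -> np.ndarray:
    """Sample one mismatched cell per cell for the matching loss.

    ``uniform`` draws any non-matching in-batch cell (mismatched pairs
    are predominantly dissimilar, so this realizes random low-similarity
    negatives); ``low_similarity``/``high_similarity`` bias the draw by
    softmax of -/+ the CLS similarities.
    """
    n = cls_similarities.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to form negative pairs")
    sign = {"uniform": 0.0, "low_similarity": -1.0, "high_similarity": 1.0}[mode]
    neg = np.empty(n, dtype=int)
    for i in range(n):
        logits = sign * cls_similarities[i].astype(float)
        logits[i] = -np.inf
        p = np.exp(logits - logits[logits > -np.inf].max())
        p[i] = 0.0
        neg[i] = rng.choice(n, p=p / p.sum())
    return neg


def _cls_row_self(tokens: Tensor, params: DecoderParams):
    """Self-attention output/weights of the CLS query row only, (B, 1, d).

    Attention rows are independent, so this equals row 0 of the full
    self-attention; the other rows are never consumed downstream.
    """
    q = tokens[:, :1, :] @ params.Wq_self
    k = tokens @ params.Wk_self
    v = tokens @ params.Wv_self
    return _multi_head_attention(q, k, v, params.heads)


def _cls_row_cross(cls_query: Tensor, key_tokens: Tensor, params: DecoderParams,
                   kv_rows: np.ndarray | None = None):
    """Cross-attention of the (already self-attended) CLS query over a
    token sequence; the CLS row of the distance mask is all zeros, so no
    mask term applies here."""
    q = cls_query @ params.Wq_cross
    k = key_tokens @ params.Wk_cross
    v = key_tokens @ params.Wv_cross
    if kv_rows is not None:
        k, v = k.take_rows(kv_rows), v.take_rows(kv_rows)
    return _multi_head_attention(q, k, v, params.heads)


def _detached_decoder(dec: DecoderParams) -> DecoderParams:
    """Parameter view without gradient tracking (cheap eval passes)."""
    out = DecoderParams.__new__(DecoderParams)
    out.d, out.heads, out.tau_cls = dec.d, dec.heads, dec.tau_cls
    out.qk_gain = dec.qk_gain
    for name in DecoderParams._ARRS:
        setattr(out, name, getattr(dec, name).detach())
    return out


def _factored_cls_self(x_np: np.ndarray, e_table: Tensor, cls_vec: Tensor,
                       params: DecoderParams):
    """CLS-row self-attention without materializing token hiddens.

    Token f of cell n is x[n, f] * E[f], so its key is x[n, f] * (E @ Wk)[f]
    and the CLS-query logit is x[n, f] * (q . (E @ Wk)[f]); the output
    aggregate likewise factors through (attn . x) @ (E @ Wv). Exact for
    heads=1 (the default decoder configuration).

    Returns (cls output B x d, attention row B x (F+1)).
    """
    if params.heads != 1:
        raise ValueError("factored CLS attention requires heads=1")
    b, f = x_np.shape
    d = params.d
    x = Tensor(x_np)
    scale = 1.0 / np.sqrt(d)
    q = cls_vec @ params.Wq_self                                   # (d,)
    k_cls = cls_vec @ params.Wk_self
    logit_cls = (q * k_cls).sum().reshape(1, 1) * Tensor(np.ones((b, 1)))
    logits_tok = x * ((e_table @ params.Wk_self) @ q)              # B x F
    attn = softmax(concat([logit_cls, logits_tok], axis=1) * scale, axis=1)
    v_cls = (cls_vec @ params.Wv_self).reshape(1, d)
    out = attn[:, :1] * v_cls + (attn[:, 1:] * x) @ (e_table @ params.Wv_self)
    return out, attn


def _factored_cls_cross(queries: Tensor, x_kv: np.ndarray, e_table: Tensor,
                        cls_vec: Tensor, params: DecoderParams):
    """CLS-row cross-attention of per-cell query vectors over count-scaled
    key/value tokens (same factorization as :func:`_factored_cls_self`).

    Returns (output B x d, attention row B x (F+1))."""
    if params.heads != 1:
        raise ValueError("factored CLS attention requires heads=1")
    b, f = x_kv.shape
    d = params.d
    x = Tensor(x_kv)
    scale = 1.0 / np.sqrt(d)
    q = queries @ params.Wq_cross                                  # B x d
    k_cls = cls_vec @ params.Wk_cross
    logit_cls = (q * k_cls).sum(axis=1, keepdims=True)             # B x 1
    logits_tok = x * (q @ (e_table @ params.Wk_cross).T)           # B x F
    attn = softmax(concat([logit_cls, logits_tok], axis=1) * scale, axis=1)
    v_cls = (cls_vec @ params.Wv_cross).reshape(1, d)
    out = attn[:, :1] * v_cls + (attn[:, 1:] * x) @ (e_table @ params.Wv_cross)
    return out, attn


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    p = softmax(logits, axis=1)
    n = logits.shape[0]
    picked = p.take_flat(np.arange(n) * logits.shape[1] + labels)
    return -(picked.log()).mean()


def _matching_loss_tensor(cls_query: Tensor, peak_tokens: Tensor,
                          params: DecoderParams, neg_idx: np.ndarray):
    """CE over equal counts of true and mismatched pairings.

    ``cls_query`` is the self-attended gene CLS row (B x 1 x d); the
    classifier reads the cross-attention CLS output for the true pairing
    and for peak sequences permuted to the sampled negatives.
    """
    b = cls_query.shape[0]
    out_pos, _ = _cls_row_cross(cls_query, peak_tokens, params)
    out_neg, _ = _cls_row_cross(cls_query, peak_tokens, params, kv_rows=neg_idx)
    logits = concat([out_pos[:, 0, :], out_neg[:, 0, :]], axis=0) @ params.Wc + params.bc
    labels = np.concatenate([np.ones(b, int), np.zeros(b, int)])
    return _cross_entropy(logits, labels), labels


def matching_loss(gene_tokens: np.ndarray, peak_tokens: np.ndarray,
                  cls_similarities: np.ndarray, params: DecoderParams,
                  rng: np.random.Generator, mode: str = "uniform",
                  return_details: bool = False):
    """RNA-ATAC matching loss on CLS-prefixed token sequences (numpy API).

    ``gene_tokens`` must already have passed self-attention (queries);
    ``peak_tokens`` carry the raw peak sequence with CLS. One hard
    negative is sampled per cell from ``cls_similarities``.
    """
    neg_idx = sample_negatives(np.asarray(cls_similarities), rng, mode)
    cls_query = Tensor(np.asarray(gene_tokens, float))[:, :1, :]
    loss, labels = _matching_loss_tensor(cls_query,
                                         Tensor(np.asarray(peak_tokens, float)),
                                         params, neg_idx)
    if return_details:
        return float(loss.data), {"negatives": neg_idx, "labels": labels}
    return float(loss.data)


def interaction_loss(cls_loss: float, match_loss: float) -> float:
    """Full decoder objective: sum of CLS contrastive and matching losses."""
    return cls_loss + match_loss


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_decoder(pretrained: EncoderParams, proc: ProcessedData,
                  config: DecoderConfig | None = None,
                  mask: AttentionMask | None = None):
    """Fine-tune the interaction decoder on a pretrained encoder.

    Returns (DecoderParams, per-epoch mean loss list). Token hiddens come
    from the teacher embedding tables, which receive gradients unless
    ``config.freeze_encoder``.
    """
    config = config or DecoderConfig()
    if mask is None:
        mask = build_attention_mask(proc.genes, proc.peaks, config.threshold_bp)
    rna, atac = proc.rna_norm, proc.atac_norm
    n = rna.shape[0]
    dec = DecoderParams(pretrained.d, heads=config.heads,
                        tau_cls=config.tau_cls, qk_gain=config.qk_gain,
                        seed=config.seed)
    e_rna, e_atac = pretrained.teacher_rna.E, pretrained.teacher_atac.E
    trainable = dec.params + ([] if config.freeze_encoder else [e_rna, e_atac])
    opt = Adam(trainable, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            if idx.size < 2:
                continue  # matching loss needs negatives
            xr, xa = rna[idx], atac[idx]
            gene_cls, _ = _factored_cls_self(xr, e_rna, dec.cls_gene, dec)
            peak_cls, _ = _factored_cls_self(xa, e_atac, dec.cls_peak, dec)

            # symmetric cross passes; their CLS outputs carry the
            # modality summaries that the contrastive term aligns
            cross_gene, _ = _factored_cls_cross(gene_cls, xa, e_atac,
                                                dec.cls_peak, dec)
            cross_peak, _ = _factored_cls_cross(peak_cls, xr, e_rna,
                                                dec.cls_gene, dec)
            l_cls = _nt_xent_tensor(cross_gene, cross_peak, config.tau_cls)

            gn = gene_cls.data / np.linalg.norm(gene_cls.data, axis=1, keepdims=True)
            pn = peak_cls.data / np.linalg.norm(peak_cls.data, axis=1, keepdims=True)
            neg_idx = sample_negatives(gn @ pn.T, rng, config.negative_mode)
            out_neg, _ = _factored_cls_cross(gene_cls, xa[neg_idx], e_atac,
                                             dec.cls_peak, dec)
            logits = concat([cross_gene, out_neg], axis=0) @ dec.Wc + dec.bc
            labels = np.concatenate([np.ones(idx.size, int), np.zeros(idx.size, int)])
            l_match = _cross_entropy(logits, labels)

            loss = l_cls + l_match
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite decoder loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return dec, history


# ---------------------------------------------------------------------------
# global attention extraction
# ---------------------------------------------------------------------------

def extract_global_attention(cross_weights_gene_query: np.ndarray,
                             cross_weights_peak_query: np.ndarray,
                             gene_ids: list[str], peak_ids: list[str],
                             mask: AttentionMask | None = None) -> GlobalAttentionMatrix:
    """Contract the two CLS attention rows over cells into a G x P matrix.

    Accepts full cross-attention weight stacks (N x (G+1) x (P+1) and
    N x (P+1) x (G+1)) or the already-extracted CLS rows (N x (P+1) and
    N x (G+1)). Masked pairs are forced to zero.
    """
    cls_rna = np.asarray(cross_weights_gene_query)
    cls_atac = np.asarray(cross_weights_peak_query)
    if cls_rna.ndim == 3:
        cls_rna = cls_rna[:, 0, :]
    if cls_atac.ndim == 3:
        cls_atac = cls_atac[:, 0, :]
    if cls_rna.shape[0] != cls_atac.shape[0]:
        raise ValueError("CLS attention row stacks disagree on cell count")
    if cls_atac.shape[1] != len(gene_ids) + 1 or cls_rna.shape[1] != len(peak_ids) + 1:
        raise ValueError("CLS attention widths do not match feature ids")
    full = cls_atac.T @ cls_rna                    # (G+1) x (P+1)
    values = full[1:, 1:].copy()
    allowed = None
    if mask is not None:
        allowed = mask.allowed
        values[~allowed] = 0.0
    return GlobalAttentionMatrix(values=values, gene_ids=list(gene_ids),
                                 peak_ids=list(peak_ids), allowed=allowed)


def compute_global_attention(pretrained: EncoderParams, dec: DecoderParams,
                             proc: ProcessedData, mask: AttentionMask | None = None,
                             chunk: int = 64) -> GlobalAttentionMatrix:
    """Eval-mode pass over all cells accumulating the global score matrix.

    The gene-query pass yields CLS attention over peaks; a symmetric
    peak-query pass with shared projections yields CLS attention over
    genes.
    """
    if mask is None:
        mask = build_attention_mask(proc.genes, proc.peaks)
    rna, atac = proc.rna_norm, proc.atac_norm
    n = rna.shape[0]
    g, p = rna.shape[1], atac.shape[1]
    full = np.zeros((g + 1, p + 1))
    e_rna = pretrained.teacher_rna.E.detach()
    e_atac = pretrained.teacher_atac.E.detach()
    dec_eval = _detached_decoder(dec)
    for lo in range(0, n, chunk):
        xr, xa = rna[lo:lo + chunk], atac[lo:lo + chunk]
        sg_cls, _ = _factored_cls_self(xr, e_rna, dec_eval.cls_gene, dec_eval)
        sp_cls, _ = _factored_cls_self(xa, e_atac, dec_eval.cls_peak, dec_eval)
        _, w_gene_q = _factored_cls_cross(sg_cls, xa, e_atac,
                                          dec_eval.cls_peak, dec_eval)
        _, w_peak_q = _factored_cls_cross(sp_cls, xr, e_rna,
                                          dec_eval.cls_gene, dec_eval)
        full += w_peak_q.data[:, :].T @ w_gene_q.data[:, :]
    values = full[1:, 1:]
    values[~mask.allowed] = 0.0
    return GlobalAttentionMatrix(values=values,
                                 gene_ids=[gn.gene_id for gn in proc.genes],
                                 peak_ids=[pk.peak_id for pk in proc.peaks],
                                 allowed=mask.allowed)
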