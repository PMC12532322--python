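"""Cross-modal NT-Xent contrastive pretraining.

A mini-batch of N paired cells yields 2N points on the embedding
hypersphere. With the interleaved index convention (point 2i is the RNA
view of cell i, point 2i+1 its ATAC view), each anchor's positive is its
other-modality twin and the loss term for an ordered pair (m, m+) is

    l(m, m+) = -log exp(s[m,m+]) / sum_{k != m} (exp(s[k,m]) + exp(s[k,m+]))

with s the temperature-scaled cosine similarity. The denominator follows
the published formula literally, so the positive's self-similarity
exp(s[m+,m+]) contributes; for N=1 identical unit-norm pairs the loss is
exactly log 2. The pretraining objective averages the teacher-pair and
student-pair losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, concat
from .data_model import EncodedCellBatch, MultiomeDataset, ProcessedData, preprocess
from .encoders import EncoderParams

PAIRING_SCHEMES = ("teacher_teacher_student_student", "crossed_teacher_student",
                   "within_modality")


@dataclass
class ContrastiveConfig:
    tau: float = 0.1
    batch_size: int = 32
    epochs: int = 20
    lr_start: float = 1e-4
    lr_end: float = 1e-6
    pairing_scheme: str = "teacher_teacher_student_student"
    dim: int = 128
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not self.lr_start >= self.lr_end > 0:
            raise ValueError("require lr_start >= lr_end > 0")
        if self.pairing_scheme not in PAIRING_SCHEMES:
            raise ValueError(f"unknown pairing scheme {self.pairing_scheme!r}")


@dataclass
class EmbeddingSet:
    """The four N x d embeddings plus the optional 2N x d joint stack."""

    Z_teacher_RNA: np.ndarray
    Z_teacher_ATAC: np.ndarray
    Z_student_RNA: np.ndarray
    Z_student_ATAC: np.ndarray
    Z_joint: np.ndarray | None = field(default=None)


# ---------------------------------------------------------------------------
# loss primitives
# ---------------------------------------------------------------------------

def cosine_sim_scaled(h1: np.ndarray, h2: np.ndarray, tau: float) -> float:
    """Temperature-scaled cosine similarity (h1 . h2) / (tau |h1| |h2|)."""
    h1, h2 = np.asarray(h1, float), np.asarray(h2, float)
    n1, n2 = np.linalg.norm(h1), np.linalg.norm(h2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm vector in cosine similarity")
    return float(h1 @ h2 / (tau * n1 * n2))


def _nt_xent_tensor(za: Tensor, zb: Tensor, tau: float) -> Tensor:
    """NT-Xent as a differentiable Tensor expression (see module docstring)."""
    n, d = za.shape
    if n == 0:
        raise ValueError("empty batch in NT-Xent")
    norms_a = np.linalg.norm(za.data, axis=1)
    norms_b = np.linalg.norm(zb.data, axis=1)
    if (norms_a == 0).any() or (norms_b == 0).any():
        raise ValueError("zero-norm embedding row in NT-Xent")
    z = concat([za.reshape(n, 1, d), zb.reshape(n, 1, d)], axis=1).reshape(2 * n, d)
    norm = (z * z).sum(axis=1, keepdims=True).sqrt()
    zn = z / norm
    s = (zn @ zn.T) * (1.0 / tau)
    c = float(s.data.max())
    e = (s - c).exp()
    colsum = e.sum(axis=0)

    two_n = 2 * n
    m = np.arange(0, two_n, 2)
    p = m + 1
    anchors = np.concatenate([m, p])
    pos = np.concatenate([p, m])
    t_anchor = colsum.take_flat(anchors)
    t_pos = colsum.take_flat(pos)
    e_self = e.take_flat(anchors * two_n + anchors)
    e_cross = e.take_flat(anchors * two_n + pos)
    denom = (t_anchor - e_self) + (t_pos - e_cross)
    s_pos = s.take_flat(anchors * two_n + pos)
    terms = (denom.log() + c) - s_pos
    return terms.sum() * (1.0 / two_n)


def nt_xent_cross_modal(z_a: np.ndarray, z_b: np.ndarray, tau: float = 0.1) -> float:
    """NT-Xent loss between row-paired embedding matrices (numpy API)."""
    return float(_nt_xent_tensor(Tensor(np.asarray(z_a, float)),
                                 Tensor(np.asarray(z_b, float)), tau).data)


def _scheme_pairs(scheme: str):
    return {
        "teacher_teacher_student_student": (
            ("Z_teacher_RNA", "Z_teacher_ATAC"), ("Z_student_RNA", "Z_student_ATAC")),
        "crossed_teacher_student": (
            ("Z_teacher_RNA", "Z_student_ATAC"), ("Z_student_RNA", "Z_teacher_ATAC")),
        "within_modality": (
            ("Z_teacher_RNA", "Z_student_RNA"), ("Z_teacher_ATAC", "Z_student_ATAC")),
    }[scheme]


def pretrain_loss(embeddings: EmbeddingSet, config: ContrastiveConfig) -> float:
    """(L_first_pair + L_second_pair) / 2 under the configured pairing scheme."""
    (a1, b1), (a2, b2) = _scheme_pairs(config.pairing_scheme)
    l1 = nt_xent_cross_modal(getattr(embeddings, a1), getattr(embeddings, b1), config.tau)
    l2 = nt_xent_cross_modal(getattr(embeddings, a2), getattr(embeddings, b2), config.tau)
    return 0.5 * (l1 + l2)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_lr(config: ContrastiveConfig, epoch: int) -> float:
    """Exponential decay from lr_start to lr_end across epochs."""
    if config.epochs <= 1:
        return config.lr_start
    frac = epoch / (config.epochs - 1)
    return config.lr_start * (config.lr_end / config.lr_start) ** frac


def train_pretrain(data: ProcessedData | MultiomeDataset,
                   config: ContrastiveConfig | None = None,
                   params: EncoderParams | None = None):
    """Contrastively pretrain the four encoders.

    Returns (EncoderParams, per-epoch mean loss list). Fully reproducible
    for a fixed config seed.
    """
    config = config or ContrastiveConfig()
    proc = data if isinstance(data, ProcessedData) else preprocess(data)
    rna, atac = proc.rna_norm, proc.atac_norm
    n = rna.shape[0]
    if params is None:
        params = EncoderParams.init(rna.shape[1], atac.shape[1], d=config.dim,
                                    dropout_rate=config.dropout_rate,
                                    seed=config.seed)
    rng = np.random.default_rng(config.seed)
    opt = Adam(params.params, lr=config.lr_start)
    (a1, b1), (a2, b2) = _scheme_pairs(config.pairing_scheme)
    history = []
    for epoch in range(config.epochs):
        opt.lr = _epoch_lr(config, epoch)
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            xr, xa = rna[idx], atac[idx]
            outs = {
                "Z_teacher_RNA": params.teacher_rna.forward(xr, train=True, rng=rng),
                "Z_teacher_ATAC": params.teacher_atac.forward(xa, train=True, rng=rng),
                "Z_student_RNA": params.student_rna.forward(xr, train=True, rng=rng),
                "Z_student_ATAC": params.student_atac.forward(xa, train=True, rng=rng),
            }
            loss = (_nt_xent_tensor(outs[a1], outs[b1], config.tau)
                    + _nt_xent_tensor(outs[a2], outs[b2], config.tau)) * 0.5
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite pretraining loss at epoch {epoch}, batch {lo // config.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return params, history


# ---------------------------------------------------------------------------
# inference-side operations
# ---------------------------------------------------------------------------

def compute_embeddings(params: EncoderParams, proc: ProcessedData,
                       with_joint: bool = True) -> EmbeddingSet:
    """Eval-mode embeddings of all four encoders (deterministic)."""
    rna, atac = proc.rna_norm, proc.atac_norm
    zt_r = params.teacher_rna.forward(rna).data
    zt_a = params.teacher_atac.forward(atac).data
    zs_r = params.student_rna.forward(rna).data
    zs_a = params.student_atac.forward(atac).data
    joint = joint_embedding(zt_r, zt_a) if with_joint else None
    return EmbeddingSet(zt_r, zt_a, zs_r, zs_a, joint)


def joint_embedding(z_teacher_rna: np.ndarray, z_teacher_atac: np.ndarray) -> np.ndarray:
    """Row-stack RNA then ATAC teacher embeddings into the 2N x d joint matrix."""
    z_teacher_rna = np.asarray(z_teacher_rna)
    z_teacher_atac = np.asarray(z_teacher_atac)
    if z_teacher_rna.shape != z_teacher_atac.shape:
        raise ValueError("joint embedding requires equal shapes")
    return np.vstack([z_teacher_rna, z_teacher_atac])


def map_query(params: EncoderParams, query: EncodedCellBatch,
              modality: str = "RNA") -> np.ndarray:
    """Embed query cells with frozen pretrained weights (reference mapping)."""
    enc = params.teacher_rna if modality == "RNA" else params.teacher_atac
    x = query.to_dense(modality)
    if x.shape[1] != enc.n_features:
        raise ValueError(
            f"query feature space ({x.shape[1]}) does not match training ({enc.n_features})")
    if x.shape[0] == 0:
        return np.empty((0, enc.d))
    return enc.forward(x).data


def alignment_uniformity(z_a: np.ndarray, z_b: np.ndarray):
    """Wang-Isola alignment/uniformity on L2-normalized embeddings.

    align = mean squared distance of positive pairs; uniform =
    log mean exp(-2 d^2) over all distinct pairs pooled across modalities.
    """
    z_a, z_b = np.asarray(z_a, float), np.asarray(z_b, float)
    if z_a.shape != z_b.shape:
        raise ValueError("paired embeddings must share shape")

    def l2norm(z):
        norms = np.linalg.norm(z, axis=1, keepdims=True)
        if (norms == 0).any():
            raise ValueError("zero-norm row")
        return z / norms

    za, zb = l2norm(z_a), l2norm(z_b)
    align = float(np.mean(np.sum((za - zb) ** 2, axis=1)))
    pool = np.vstack([za, zb])
    if pool.shape[0] < 2:
        raise ValueError("uniformity undefined for fewer than 2 points")
    sq = np.sum((pool[:, None, :] - pool[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(pool.shape[0], k=1)
    uniform = float(np.log(np.mean(np.exp(-2.0 * sq[iu]))))
    return align, uniform
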