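"""Asymmetric teacher-student encoder pairs for RNA and ATAC.

The teacher embeds each nonzero feature token (embedding row scaled by
its normalized count), aggregates tokens with a tanh-MLP / context-vector
attention, and projects the cell vector through batchnorm, dropout and a
ReLU dense layer. The student is a plain batchnorm -> dropout -> ReLU
dense map on the dense count vector. Both output d-dimensional cell
embeddings (d = 128 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from ._autodiff import Tensor, softmax
from .data_model import EncodedCellBatch

MASK_NEG = -1e9


@dataclass
class TokenHidden:
    """Count-weighted token embeddings (cells x features x d)."""

    values: np.ndarray
    modality: str


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class BatchNorm:
    """Batch normalization with running statistics for inference.

    Single-cell training batches (N=1) skip the batch-statistic update and
    fall back to running statistics.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train and x.shape[0] > 1:
            mean = x.mean(axis=0, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            norm = centered / (var + self.eps).sqrt()
        else:
            norm = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return norm * self.gamma + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]


class TeacherEncoder:
    """Hierarchical-attention encoder over (index, count) token streams."""

    def __init__(self, n_features: int, d: int, dropout_rate: float,
                 rng: np.random.Generator, u: Tensor | None = None):
        self.n_features = n_features
        self.d = d
        self.dropout_rate = dropout_rate
        self.E = Tensor(_glorot(rng, n_features, d), requires_grad=True)
        self.Wa = Tensor(_glorot(rng, d, d), requires_grad=True)
        self.ba = Tensor(np.zeros(d), requires_grad=True)
        self.u = u if u is not None else Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(d), size=d), requires_grad=True)
        self.bn = BatchNorm(d)
        self.W = Tensor(_glorot(rng, d, d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)

    def token_hidden(self, x_dense: np.ndarray) -> Tensor:
        """Count-weighted embeddings, N x F x d; zero-count tokens are zero."""
        x = Tensor(np.asarray(x_dense))
        return x.reshape(x.shape[0], x.shape[1], 1) * self.E.reshape(
            1, self.n_features, self.d)

    def _attention(self, x_dense: np.ndarray) -> Tensor:
        """Masked softmax attention over a cell's nonzero tokens, N x F.

        Token hiddens are count-scaled embedding rows, so the tanh-MLP
        input factors as count * (E @ Wa)[f] without materializing the
        N x F x d hidden stack in the matmul.
        """
        n, f = x_dense.shape
        x = Tensor(x_dense)
        ew = self.E @ self.Wa                                      # F x d
        pre = x.reshape(n, f, 1) * ew.reshape(1, f, self.d) + self.ba
        scores = pre.tanh() @ self.u                               # N x F
        scores = scores + Tensor(np.where(x_dense != 0, 0.0, MASK_NEG))
        return softmax(scores, axis=1)

    def forward(self, x_dense: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Cell embeddings, N x d (Tensor; backprop when params require grad)."""
        x_dense = np.asarray(x_dense)
        if x_dense.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {x_dense.shape[1]}")
        attn = self._attention(x_dense)
        # sum_f attn_f * (x_f * E_f)  ==  (attn . x) @ E
        cell = (attn * Tensor(x_dense)) @ self.E
        cell = self.bn(cell, train)
        cell = dropout(cell, self.dropout_rate, rng, train)
        return ((cell @ self.W) + self.b).relu()

    def attention_weights(self, x_dense: np.ndarray) -> np.ndarray:
        return self._attention(np.asarray(x_dense)).data

    @property
    def params(self):
        own = [self.E, self.Wa, self.ba, self.W, self.b] + self.bn.params
        if self.u.requires_grad:
            own.append(self.u)
        return own


class StudentEncoder:
    """Dense encoder: batchnorm -> dropout -> ReLU dense to d dims."""

    def __init__(self, n_features: int, d: int, dropout_rate: float,
                 rng: np.random.Generator):
        self.n_features = n_features
        self.d = d
        self.dropout_rate = dropout_rate
        self.bn = BatchNorm(n_features)
        self.W = Tensor(_glorot(rng, n_features, d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)

    def forward(self, x_dense: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        x_dense = np.asarray(x_dense)
        if x_dense.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {x_dense.shape[1]}")
        h = self.bn(Tensor(x_dense), train)
        h = dropout(h, self.dropout_rate, rng, train)
        return ((h @ self.W) + self.b).relu()

    @property
    def params(self):
        return [self.W, self.b] + self.bn.params


@dataclass
class EncoderParams:
    """The four encoders of the teacher-student pair for both modalities."""

    teacher_rna: TeacherEncoder
    teacher_atac: TeacherEncoder
    student_rna: StudentEncoder
    student_atac: StudentEncoder
    d: int
    dropout_rate: float
    init_seed: int

    @classmethod
    def init(cls, n_genes: int, n_peaks: int, d: int = 128,
             dropout_rate: float = 0.1, seed: int = 0,
             share_context: bool = False) -> "EncoderParams":
        rng = np.random.default_rng(seed)
        t_rna = TeacherEncoder(n_genes, d, dropout_rate, rng)
        u = t_rna.u if share_context else None
        t_atac = TeacherEncoder(n_peaks, d, dropout_rate, rng, u=u)
        s_rna = StudentEncoder(n_genes, d, dropout_rate, rng)
        s_atac = StudentEncoder(n_peaks, d, dropout_rate, rng)
        return cls(t_rna, t_atac, s_rna, s_atac, d, dropout_rate, seed)

    @property
    def params(self):
        seen, out = set(), []
        for enc in (self.teacher_rna, self.teacher_atac,
                    self.student_rna, self.student_atac):
            for p in enc.params:
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs.update({"d": self.d, "dropout_rate": self.dropout_rate,
                            "init_seed": self.init_seed,
                            "n_genes": self.teacher_rna.n_features,
                            "n_peaks": self.teacher_atac.n_features,
                            "shared_context": self.teacher_rna.u is self.teacher_atac.u})
            for name, enc in (("teacher_rna", self.teacher_rna),
                              ("teacher_atac", self.teacher_atac)):
                g = f.create_group(name)
                for key in ("E", "Wa", "ba", "u", "W", "b"):
                    g.create_dataset(key, data=getattr(enc, key).data)
                _save_bn(g, enc.bn)
            for name, enc in (("student_rna", self.student_rna),
                              ("student_atac", self.student_atac)):
                g = f.create_group(name)
                for key in ("W", "b"):
                    g.create_dataset(key, data=getattr(enc, key).data)
                _save_bn(g, enc.bn)

    @classmethod
    def load(cls, path) -> "EncoderParams":
        with h5py.File(path, "r") as f:
            d = int(f.attrs["d"])
            dr = float(f.attrs["dropout_rate"])
            seed = int(f.attrs["init_seed"])
            params = cls.init(int(f.attrs["n_genes"]), int(f.attrs["n_peaks"]),
                              d=d, dropout_rate=dr, seed=seed,
                              share_context=bool(f.attrs["shared_context"]))
            for name, enc in (("teacher_rna", params.teacher_rna),
                              ("teacher_atac", params.teacher_atac)):
                g = f[name]
                for key in ("E", "Wa", "ba", "u", "W", "b"):
                    getattr(enc, key).data[...] = g[key][:]
                _load_bn(g, enc.bn)
            for name, enc in (("student_rna", params.student_rna),
                              ("student_atac", params.student_atac)):
                g = f[name]
                for key in ("W", "b"):
                    getattr(enc, key).data[...] = g[key][:]
                _load_bn(g, enc.bn)
        return params


def _save_bn(group, bn: BatchNorm) -> None:
    g = group.create_group("bn")
    g.create_dataset("gamma", data=bn.gamma.data)
    g.create_dataset("beta", data=bn.beta.data)
    g.create_dataset("running_mean", data=bn.running_mean)
    g.create_dataset("running_var", data=bn.running_var)


def _load_bn(group, bn: BatchNorm) -> None:
    g = group["bn"]
    bn.gamma.data[...] = g["gamma"][:]
    bn.beta.data[...] = g["beta"][:]
    bn.running_mean[...] = g["running_mean"][:]
    bn.running_var[...] = g["running_var"][:]


# ---------------------------------------------------------------------------
# functional API
# ---------------------------------------------------------------------------

def _pick_teacher(params: EncoderParams, modality: str) -> TeacherEncoder:
    if modality == "RNA":
        return params.teacher_rna
    if modality == "ATAC":
        return params.teacher_atac
    raise ValueError(f"unknown modality {modality!r}")


def _pick_student(params: EncoderParams, modality: str) -> StudentEncoder:
    return params.student_rna if modality == "RNA" else params.student_atac


def teacher_forward(batch: EncodedCellBatch, params: EncoderParams,
                    modality: str, train_mode: bool = False,
                    rng: np.random.Generator | None = None):
    """Eval/train forward pass of one teacher; numpy outputs.

    Returns (:class:`TokenHidden`, N x d cell embeddings).
    """
    enc = _pick_teacher(params, modality)
    x = batch.to_dense(modality)
    empty = ~np.any(x != 0, axis=1)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty cell(s): zero aggregate embedding")
    cell = enc.forward(x, train=train_mode, rng=rng)
    return TokenHidden(values=enc.token_hidden(x).data, modality=modality), cell.data


def student_forward(values: np.ndarray, params: EncoderParams, modality: str,
                    train_mode: bool = False,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Eval/train forward pass of one student on a dense N x F matrix."""
    enc = _pick_student(params, modality)
    return enc.forward(np.asarray(values), train=train_mode, rng=rng).data
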