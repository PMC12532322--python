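"""ATAC -> RNA modality prediction and chromatin-potential residuals.

A two-layer MLP (hidden width 1,000, ReLU) regresses the normalized
expression matrix from the student-ATAC cell embeddings under an MSE
objective. The residual matrix (predicted minus measured, both on the
log-normalized scale) is the chromatin-potential readout: genes whose
accessibility leads their transcription accumulate systematic residual
along pseudotime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import argrelextrema

from ._autodiff import Adam, Tensor
from .data_model import ProcessedData
from .encoders import EncoderParams, StudentEncoder

HIDDEN_UNITS = 1000


class PredictionHead:
    """MLP regression head: d -> 1000 (ReLU) -> G."""

    def __init__(self, d: int, n_genes: int, seed: int = 0,
                 hidden_units: int = HIDDEN_UNITS):
        rng = np.random.default_rng(seed)
        def glorot(fi, fo):
            lim = np.sqrt(6.0 / (fi + fo))
            return rng.uniform(-lim, lim, size=(fi, fo))
        self.W1 = Tensor(glorot(d, hidden_units), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden_units), requires_grad=True)
        self.W2 = Tensor(glorot(hidden_units, n_genes), requires_grad=True)
        self.b2 = Tensor(np.zeros(n_genes), requires_grad=True)
        self.n_genes = n_genes
        self.trained = False

    def forward(self, z: np.ndarray | Tensor) -> Tensor:
        z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, float))
        return ((z @ self.W1 + self.b1).relu() @ self.W2) + self.b2

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]


def fine_tune_predictor(pretrained: EncoderParams, proc: ProcessedData,
                        epochs: int = 40, from_scratch: bool = False,
                        batch_size: int = 32, lr: float = 1e-3,
                        seed: int = 0) -> PredictionHead:
    """Train the prediction head on (frozen) student-ATAC embeddings.

    ``from_scratch=True`` is the de-novo ablation: embeddings come from a
    freshly initialized, untrained student encoder instead of the
    pretrained one.
    """
    if from_scratch:
        rng_init = np.random.default_rng(seed + 1)
        student = StudentEncoder(proc.atac_norm.shape[1], pretrained.d,
                                 pretrained.dropout_rate, rng_init)
        z_atac = student.forward(proc.atac_norm).data
    else:
        z_atac = pretrained.student_atac.forward(proc.atac_norm).data
    target = proc.rna_norm
    head = PredictionHead(pretrained.d, target.shape[1], seed=seed)
    opt = Adam(head.params, lr=lr)
    rng = np.random.default_rng(seed)
    n = z_atac.shape[0]
    for epoch in range(epochs):
        perm = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = perm[lo:lo + batch_size]
            pred = head.forward(z_atac[idx])
            diff = pred - Tensor(target[idx])
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite prediction loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
    head.trained = True
    return head


def predict_expression(head: PredictionHead, z_student_atac: np.ndarray) -> np.ndarray:
    """Predicted normalized expression, N x G (deterministic eval)."""
    if not head.trained:
        raise ValueError("prediction head has not been trained")
    return head.forward(np.asarray(z_student_atac, float)).data


@dataclass
class ResidualMatrix:
    """Predicted-minus-measured expression with per-gene dispersion summary."""

    values: np.ndarray
    gene_ids: list[str]
    gene_std: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError("residual columns do not match gene ids")
        self.gene_std = self.values.std(axis=0)


def compute_residuals(pred: np.ndarray, measured: np.ndarray,
                      gene_ids: list[str] | None = None) -> ResidualMatrix:
    """Elementwise predicted - measured (both normalized)."""
    pred, measured = np.asarray(pred, float), np.asarray(measured, float)
    if pred.shape != measured.shape:
        raise ValueError("prediction/measurement shape mismatch")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(pred.shape[1])]
    return ResidualMatrix(values=pred - measured, gene_ids=list(gene_ids))


def _plateau_extrema(v: np.ndarray, weak, strict) -> np.ndarray:
    """Interior extremum indices, tolerating flat plateaus at the extremum.

    ``argrelextrema`` with a strict comparator misses e.g. a symmetric
    peak sampled at two equal grid points; candidates from the weak
    comparator are grouped into runs, and a run qualifies when strictly
    exceeded-from and dropped-to on both sides (so constant curves yield
    nothing). One index (run center) is reported per plateau.
    """
    cand = argrelextrema(v, weak)[0]
    if cand.size == 0:
        return cand
    out = []
    splits = np.flatnonzero(np.diff(cand) > 1)
    for run in np.split(cand, splits + 1):
        a, b = run[0], run[-1]
        if a > 0 and b < len(v) - 1 and strict(v[a], v[a - 1]) and strict(v[b], v[b + 1]):
            out.append(run[len(run) // 2])
    return np.asarray(out, dtype=int)


def residual_trend(residuals: ResidualMatrix, pseudotime: np.ndarray,
                   gene: int | str, n_grid: int = 200,
                   std_quantile: float = 0.90):
    """Smooth one gene's residual along pseudotime and locate extrema.

    Fits a GCV-penalized smoothing spline (duplicated pseudotimes are
    collapsed to their mean residual first), evaluates it on ``n_grid``
    points, and reports interior local maxima/minima. The gene is flagged
    when its residual standard deviation exceeds the ``std_quantile``
    quantile across genes.

    Returns (grid, smoothed values, {"maxima": t, "minima": t}, flagged).
    """
    if isinstance(gene, str):
        gene = residuals.gene_ids.index(gene)
    pseudotime = np.asarray(pseudotime, float)
    y = residuals.values[:, gene]
    if pseudotime.shape[0] != y.shape[0]:
        raise ValueError("pseudotime must cover every cell")
    if pseudotime.shape[0] < 10:
        raise ValueError("refusing to smooth fewer than 10 cells")
    order = np.argsort(pseudotime)
    t_sorted, y_sorted = pseudotime[order], y[order]
    t_unique, inverse = np.unique(t_sorted, return_inverse=True)
    y_mean = np.bincount(inverse, weights=y_sorted) / np.bincount(inverse)
    if t_unique.size < 4:
        raise ValueError("need at least 4 distinct pseudotime values")
    if np.allclose(y_mean, y_mean[0]):
        grid = np.linspace(t_unique[0], t_unique[-1], n_grid)
        smooth = np.full(n_grid, y_mean[0])
    else:
        spline = make_smoothing_spline(t_unique, y_mean)
        grid = np.linspace(t_unique[0], t_unique[-1], n_grid)
        smooth = spline(grid)
    maxima = _plateau_extrema(smooth, np.greater_equal, np.greater)
    minima = _plateau_extrema(smooth, np.less_equal, np.less)
    threshold = np.quantile(residuals.gene_std, std_quantile)
    flagged = bool(residuals.gene_std[gene] > threshold)
    return grid, smooth, {"maxima": grid[maxima], "minima": grid[minima]}, flagged
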