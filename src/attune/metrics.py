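"""Integration and prediction evaluation metrics.

Integration metrics operate on embeddings with Euclidean distances and
k = 30 neighbors by default: FOSCTTM (fraction of other-modality cells
strictly closer than the true match, lower is better), mean average
precision of same-type neighbors, scaled cell-type/batch silhouettes,
neighbor consistency (Jaccard retention of kNN sets), Seurat alignment
score, and graph connectivity. Composites follow the 0.6 x biology +
0.4 x mixing weighting; min-max scaling across peer methods is the
identity when a method is evaluated alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, rankdata
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

DEFAULT_K = 30


@dataclass
class MetricReport:
    map: float
    cell_type_asw: float
    batch_asw: float
    nc: float
    sas: float
    gc: float
    foscttm: float
    alignment: float | None = None
    uniformity: float | None = None
    biology_conservation: float | None = None
    omics_mixing: float | None = None
    overall: float | None = None
    rmse: float | None = None
    pearson_genewise: float | None = None
    spearman_genewise: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# ---------------------------------------------------------------------------
# alignment metrics
# ---------------------------------------------------------------------------

def foscttm(z_a: np.ndarray, z_b: np.ndarray) -> float:
    """Fraction of other-modality samples strictly closer than the true match."""
    z_a, z_b = np.asarray(z_a, float), np.asarray(z_b, float)
    if z_a.shape != z_b.shape:
        raise ValueError("paired embeddings must share shape")
    n = z_a.shape[0]
    if n < 2:
        raise ValueError("FOSCTTM needs at least 2 cells")
    d = np.linalg.norm(z_a[:, None, :] - z_b[None, :, :], axis=-1)
    true = np.diag(d)
    frac_a = (d < true[:, None]).sum(axis=1) / (n - 1)   # a_i vs all b_j
    frac_b = (d < true[None, :]).sum(axis=0) / (n - 1)   # b_j vs all a_i
    return float((frac_a.mean() + frac_b.mean()) / 2.0)


def _knn_indices(z: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors (self excluded) per row."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    idx = nn.kneighbors(z, return_distance=False)
    # drop self wherever it appears in the neighbor list
    out = np.empty((z.shape[0], k), dtype=int)
    for i, row in enumerate(idx):
        out[i] = row[row != i][:k]
    return out


def mean_average_precision(z_joint: np.ndarray, cell_types: np.ndarray,
                           k: int = DEFAULT_K) -> float:
    """Mean over cells of the average precision of same-type k-neighbors."""
    z_joint = np.asarray(z_joint, float)
    cell_types = np.asarray(cell_types)
    if len(np.unique(cell_types)) < 2:
        warnings.warn("single cell type: MAP is trivially 1")
        return 1.0
    k = min(k, z_joint.shape[0] - 1)
    nbrs = _knn_indices(z_joint, k)
    same = cell_types[nbrs] == cell_types[:, None]
    ranks = np.arange(1, k + 1)
    cum_hits = np.cumsum(same, axis=1)
    precision_at = cum_hits / ranks
    n_same = same.sum(axis=1)
    ap = np.where(n_same > 0, (precision_at * same).sum(axis=1) / np.maximum(n_same, 1), 0.0)
    return float(ap.mean())


def silhouette_scores(z_joint: np.ndarray, cell_types: np.ndarray,
                      modality_labels: np.ndarray):
    """(cell_type_asw, batch_asw), both scaled to [0, 1].

    cell_type_asw = (mean silhouette over cell-type labels + 1) / 2;
    batch_asw = mean over cell types of mean (1 - |silhouette|) computed
    on modality labels within the type (scIB formulation).
    """
    z_joint = np.asarray(z_joint, float)
    cell_types = np.asarray(cell_types)
    modality_labels = np.asarray(modality_labels)
    if len(np.unique(cell_types)) < 2:
        raise ValueError("cell-type ASW needs at least 2 types")
    asw_type = (silhouette_samples(z_joint, cell_types).mean() + 1.0) / 2.0
    per_type = []
    for ct in np.unique(cell_types):
        sel = cell_types == ct
        mods = modality_labels[sel]
        if len(np.unique(mods)) < 2:
            continue
        sil = silhouette_samples(z_joint[sel], mods)
        per_type.append(np.mean(1.0 - np.abs(sil)))
    if not per_type:
        raise ValueError("no cell type contains both modalities")
    return float(asw_type), float(np.mean(per_type))


def neighbor_consistency(z_joint_per_modality: np.ndarray | list,
                         z_unimodal_pre: np.ndarray | list,
                         k: int = DEFAULT_K) -> float:
    """Mean Jaccard overlap of kNN sets before vs after integration.

    Accepts one (post, pre) embedding pair or lists of row-aligned pairs
    (one per modality); the per-modality means are averaged.
    """
    if isinstance(z_joint_per_modality, np.ndarray):
        z_joint_per_modality = [z_joint_per_modality]
        z_unimodal_pre = [z_unimodal_pre]
    vals = []
    for post, pre in zip(z_joint_per_modality, z_unimodal_pre):
        post, pre = np.asarray(post, float), np.asarray(pre, float)
        if post.shape[0] != pre.shape[0]:
            raise ValueError("pre/post embeddings not row-aligned")
        if k >= post.shape[0]:
            raise ValueError("k must be smaller than the cell count")
        nb_post = _knn_indices(post, k)
        nb_pre = _knn_indices(pre, k)
        jac = []
        for a, b in zip(nb_post, nb_pre):
            inter = len(set(a) & set(b))
            jac.append(inter / (2 * k - inter))
        vals.append(np.mean(jac))
    return float(np.mean(vals))


def seurat_alignment_score(z_joint: np.ndarray, modality_labels: np.ndarray,
                           k: int = DEFAULT_K, n_subsample: int | None = None,
                           seed: int = 0) -> float:
    """1 - (mean same-modality neighbor count - k/M) / (k - k/M), clipped to [0,1].

    Groups are subsampled to equal sizes before the kNN query.
    """
    z_joint = np.asarray(z_joint, float)
    modality_labels = np.asarray(modality_labels)
    groups = np.unique(modality_labels)
    m = len(groups)
    if m < 2:
        raise ValueError("alignment score needs at least 2 modalities")
    rng = np.random.default_rng(seed)
    min_size = min((modality_labels == g).sum() for g in groups)
    size = min(n_subsample or min_size, min_size)
    keep = np.concatenate([
        rng.choice(np.flatnonzero(modality_labels == g), size=size, replace=False)
        for g in groups])
    z, labs = z_joint[keep], modality_labels[keep]
    k_eff = min(k, z.shape[0] - 1)
    nbrs = _knn_indices(z, k_eff)
    same = (labs[nbrs] == labs[:, None]).sum(axis=1).mean()
    expected = k_eff / m
    score = 1.0 - (same - expected) / (k_eff - expected)
    return float(np.clip(score, 0.0, 1.0))


def graph_connectivity(z_joint: np.ndarray, cell_types: np.ndarray,
                       k: int = DEFAULT_K) -> float:
    """Mean over types of the largest-connected-component fraction of the
    type-restricted kNN graph."""
    from scipy.sparse.csgraph import connected_components
    from sklearn.neighbors import kneighbors_graph

    z_joint = np.asarray(z_joint, float)
    cell_types = np.asarray(cell_types)
    fractions = []
    for ct in np.unique(cell_types):
        sel = np.flatnonzero(cell_types == ct)
        if sel.size == 1:
            fractions.append(1.0)
            continue
        k_eff = min(k, sel.size - 1)
        graph = kneighbors_graph(z_joint[sel], n_neighbors=k_eff)
        n_comp, labels = connected_components(graph, directed=False)
        largest = np.bincount(labels).max()
        fractions.append(largest / sel.size)
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

_BIO_KEYS = ("map", "cell_type_asw", "nc")
_OMICS_KEYS = ("sas", "batch_asw", "gc")


def composite_scores(components: dict, peer_values: dict | None = None):
    """(biology_conservation, omics_mixing, overall).

    With ``peer_values`` (component -> list of peer-method values
    including this method's), each component is min-max scaled over the
    peers; alone, scale() is the identity. overall = 0.6 bio + 0.4 omics.
    """
    missing = [key for key in _BIO_KEYS + _OMICS_KEYS if key not in components]
    if missing:
        raise ValueError(f"missing components: {missing}")

    def scale(key):
        val = components[key]
        if peer_values is None or key not in peer_values:
            return val
        peers = np.asarray(peer_values[key], float)
        lo, hi = peers.min(), peers.max()
        return 0.5 if hi == lo else (val - lo) / (hi - lo)

    bio = float(np.mean([scale(key) for key in _BIO_KEYS]))
    omics = float(np.mean([scale(key) for key in _OMICS_KEYS]))
    return bio, omics, 0.6 * bio + 0.4 * omics


# ---------------------------------------------------------------------------
# prediction metrics
# ---------------------------------------------------------------------------

def prediction_metrics(pred: np.ndarray, truth: np.ndarray):
    """(rmse, mean gene-wise Pearson, mean gene-wise Spearman).

    Constant genes (in either matrix) are excluded from the correlation
    means; their count is reported via a warning.
    """
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    const = (pred.std(axis=0) == 0) | (truth.std(axis=0) == 0)
    if const.all():
        raise ValueError("all genes constant: correlations undefined")
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s) excluded from correlations")
    cols = np.flatnonzero(~const)
    pearsons = [pearsonr(pred[:, j], truth[:, j])[0] for j in cols]
    spearmans = [pearsonr(rankdata(pred[:, j]), rankdata(truth[:, j]))[0] for j in cols]
    return rmse, float(np.mean(pearsons)), float(np.mean(spearmans))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def evaluate_integration(z_rna: np.ndarray, z_atac: np.ndarray,
                         cell_types: np.ndarray,
                         z_pre_rna: np.ndarray | None = None,
                         z_pre_atac: np.ndarray | None = None,
                         k: int = DEFAULT_K) -> MetricReport:
    """All integration metrics on paired embeddings with the joint stack."""
    from .pretrain import alignment_uniformity, joint_embedding

    z_joint = joint_embedding(z_rna, z_atac)
    types2 = np.concatenate([cell_types, cell_types])
    mods = np.array(["RNA"] * len(z_rna) + ["ATAC"] * len(z_atac))
    asw_type, asw_batch = silhouette_scores(z_joint, types2, mods)
    if z_pre_rna is not None:
        nc = neighbor_consistency([z_rna, z_atac], [z_pre_rna, z_pre_atac],
                                  k=min(k, len(z_rna) - 1))
    else:
        nc = neighbor_consistency(z_joint, z_joint, k=min(k, len(z_joint) - 1))
    align, uniform = alignment_uniformity(z_rna, z_atac)
    report = MetricReport(
        map=mean_average_precision(z_joint, types2, k=k),
        cell_type_asw=asw_type,
        batch_asw=asw_batch,
        nc=nc,
        sas=seurat_alignment_score(z_joint, mods, k=k),
        gc=graph_connectivity(z_joint, types2, k=k),
        foscttm=foscttm(z_rna, z_atac),
        alignment=align,
        uniformity=uniform,
    )
    bio, omics, overall = composite_scores(report.as_dict())
    report.biology_conservation = bio
    report.omics_mixing = omics
    report.overall = overall
    return report
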