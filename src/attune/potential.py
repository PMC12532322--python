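"""Lineage-resolved downstream analyses on the integrated embeddings.

Cells are aggregated into pseudotime-ordered pseudo-bulk groups; peak
profiles over the groups are soft-clustered with fuzzy c-means (the
fuzzifier is estimated from data dimensionality, Schwaemmle-Jensen
formula); cluster-associated genes are ranked by mean Spearman
correlation against GC/coverage-matched background peaks; per-cell
cross-modal cosine distances flag actively transitioning cells; and
differentially expressed genes are called by one-vs-rest Wilcoxon tests
with Benjamini-Hochberg correction and a log-fold-change cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .regulatory import kneedle_elbow


# ---------------------------------------------------------------------------
# pseudo-bulk aggregation
# ---------------------------------------------------------------------------

@dataclass
class PseudoBulkMatrix:
    """Group x feature standardized means over pseudotime bins."""

    values: np.ndarray               # groups x features, z-scored per feature
    raw_means: np.ndarray            # groups x features, unstandardized
    feature_indices: np.ndarray      # columns kept (constant features dropped)
    group_sizes: np.ndarray
    composition: pd.DataFrame | None = None


def pseudobulk(features: np.ndarray, pseudotime: np.ndarray, n_groups: int = 10,
               cell_types: np.ndarray | None = None) -> PseudoBulkMatrix:
    """Sort cells by pseudotime, split into near-equal bins, average, z-score.

    Remainder cells go to the earliest bins. Features constant across
    groups are dropped with a warning. With ``cell_types`` a group-by-type
    composition table is emitted.
    """
    features = np.asarray(features, float)
    pseudotime = np.asarray(pseudotime, float)
    n = features.shape[0]
    if pseudotime.shape[0] != n:
        raise ValueError("pseudotime must cover every cell")
    if n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds {n} cells")
    order = np.argsort(pseudotime, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = np.array([base + (1 if i < rem else 0) for i in range(n_groups)])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    means = np.stack([features[order[lo:hi]].mean(axis=0)
                      for lo, hi in zip(bounds[:-1], bounds[1:])])
    sd = means.std(axis=0, ddof=0)
    keep = np.flatnonzero(sd > 0)
    if keep.size < means.shape[1]:
        warnings.warn(f"{means.shape[1] - keep.size} constant feature(s) dropped "
                      "from pseudo-bulk standardization")
    z = (means[:, keep] - means[:, keep].mean(axis=0)) / sd[keep]
    composition = None
    if cell_types is not None:
        cell_types = np.asarray(cell_types)
        rows = []
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            counts = pd.Series(cell_types[order[lo:hi]]).value_counts()
            counts.name = f"group{i}"
            rows.append(counts)
        composition = pd.DataFrame(rows).fillna(0).astype(int)
    return PseudoBulkMatrix(values=z, raw_means=means, feature_indices=keep,
                            group_sizes=sizes, composition=composition)


# ---------------------------------------------------------------------------
# fuzzy c-means soft clustering
# ---------------------------------------------------------------------------

def estimate_fuzzifier(n_samples: int, n_dims: int) -> float:
    """Schwaemmle-Jensen data-driven fuzzifier estimate."""
    d = float(n_dims)
    n = float(n_samples)
    m = 1.0 + (1418.0 / n + 22.05) * d ** -2 + \
        (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    return float(m)


def _fcm(x: np.ndarray, c: int, m: float, rng: np.random.Generator,
         max_iter: int = 300, tol: float = 1e-6):
    """Bezdek fuzzy c-means. Returns (membership n x c, centroids c x p)."""
    n = x.shape[0]
    u = rng.dirichlet(np.ones(c), size=n)
    for _ in range(max_iter):
        um = u ** m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        dist = np.linalg.norm(x[:, None, :] - centroids[None, :, :], axis=-1)
        zero = dist < 1e-12
        if zero.any():
            u_new = np.where(zero, 1.0, 0.0)
            rows = zero.any(axis=1)
            with np.errstate(divide="ignore"):
                ratio = (dist[:, :, None] / dist[:, None, :]) ** (2.0 / (m - 1.0))
            u_other = 1.0 / ratio.sum(axis=2)
            u_new[~rows] = u_other[~rows]
            u_new /= u_new.sum(axis=1, keepdims=True)
        else:
            ratio = (dist[:, :, None] / dist[:, None, :]) ** (2.0 / (m - 1.0))
            u_new = 1.0 / ratio.sum(axis=2)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    um = u ** m
    centroids = (um.T @ x) / um.sum(axis=0)[:, None]
    return u, centroids


@dataclass
class SoftClusterResult:
    membership: np.ndarray           # peaks x c, rows sum to 1
    centroids: np.ndarray            # c x groups
    chosen_c: int
    alpha_core_members: dict[int, np.ndarray]
    fuzzifier: float
    min_centroid_distance: dict[int, float]


def soft_cluster(pbulk: PseudoBulkMatrix, c_range: tuple[int, int] = (2, 20),
                 acore: float = 0.5, seed: int = 0,
                 fuzzifier: float | None = None,
                 chosen_c: int | None = None) -> SoftClusterResult:
    """Fuzzy c-means over standardized peak profiles (peaks as samples).

    The cluster number is chosen by the elbow (kneedle) of the minimum
    inter-centroid distance as c grows, unless ``chosen_c`` overrides it.
    Alpha cores keep peaks with membership > ``acore`` in a cluster.
    """
    x = pbulk.values.T               # peaks x groups
    n_peaks = x.shape[0]
    c_lo, c_hi = c_range
    c_hi = min(c_hi, n_peaks - 1)
    if c_lo > c_hi:
        raise ValueError("cluster range empty for this peak count")
    if np.allclose(x, x[0]):
        warnings.warn("all peak profiles identical: degenerate single cluster")
    m = fuzzifier if fuzzifier is not None else estimate_fuzzifier(n_peaks, x.shape[1])
    rng = np.random.default_rng(seed)
    runs, min_dists = {}, {}
    for c in range(c_lo, c_hi + 1):
        u, cent = _fcm(x, c, m, np.random.default_rng(rng.integers(2 ** 31)))
        pair_d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
        iu = np.triu_indices(c, k=1)
        min_dists[c] = float(pair_d[iu].min()) if iu[0].size else np.inf
        runs[c] = (u, cent)
    if chosen_c is None:
        cs = sorted(min_dists)
        chosen_c = cs[kneedle_elbow(np.array([min_dists[c] for c in cs]))]
    u, cent = runs[chosen_c]
    cores = {k: np.flatnonzero(u[:, k] > acore) for k in range(chosen_c)}
    return SoftClusterResult(membership=u, centroids=cent, chosen_c=chosen_c,
                             alpha_core_members=cores, fuzzifier=m,
                             min_centroid_distance=min_dists)


# ---------------------------------------------------------------------------
# cluster-associated genes with matched background
# ---------------------------------------------------------------------------

def _spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlations between columns of a (n x p) and b (n x q)."""
    ra = np.apply_along_axis(rankdata, 0, a)
    rb = np.apply_along_axis(rankdata, 0, b)
    ra = (ra - ra.mean(axis=0)) / ra.std(axis=0)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
    return ra.T @ rb / a.shape[0]


def match_background_peaks(peak_idx: np.ndarray, gc: np.ndarray,
                           coverage: np.ndarray, n_background: int = 50,
                           n_bins: int = 10, seed: int = 0) -> dict[int, np.ndarray]:
    """Sample background peaks per focal peak from the same GC x coverage
    decile bin (excluding the focal peak); bins too small are widened to
    the GC decile, then to all peaks, with a warning."""
    rng = np.random.default_rng(seed)
    gc_bin = np.clip(np.searchsorted(np.quantile(gc, np.linspace(0, 1, n_bins + 1)[1:-1]),
                                     gc, side="right"), 0, n_bins - 1)
    cov_bin = np.clip(np.searchsorted(np.quantile(coverage,
                                                  np.linspace(0, 1, n_bins + 1)[1:-1]),
                                      coverage, side="right"), 0, n_bins - 1)
    all_idx = np.arange(len(gc))
    out = {}
    for focal in peak_idx:
        pool = all_idx[(gc_bin == gc_bin[focal]) & (cov_bin == cov_bin[focal])]
        pool = pool[pool != focal]
        if pool.size == 0:
            warnings.warn(f"widening background bin for peak {focal}")
            pool = all_idx[gc_bin == gc_bin[focal]]
            pool = pool[pool != focal]
        if pool.size == 0:
            pool = all_idx[all_idx != focal]
        out[focal] = rng.choice(pool, size=n_background, replace=pool.size < n_background)
    return out


def cluster_associated_genes(cluster_peaks: np.ndarray, pbulk_peaks: PseudoBulkMatrix,
                             pbulk_genes: PseudoBulkMatrix, gc: np.ndarray,
                             coverage: np.ndarray, n_background: int = 50,
                             seed: int = 0) -> pd.DataFrame:
    """Rank genes by mean Spearman correlation with a peak cluster.

    The null statistic repeats the computation over GC/coverage-matched
    background peaks; a one-sided Wilcoxon rank-sum test per gene
    (cluster correlations > background correlations) is BH-adjusted.
    Returns a DataFrame (gene column index, mean_rho, bg_rho, pvalue,
    p_adjusted) sorted by mean_rho descending.
    """
    cluster_peaks = np.asarray(cluster_peaks, int)
    if cluster_peaks.size == 0:
        raise ValueError("empty peak cluster")
    bg_map = match_background_peaks(cluster_peaks, gc, coverage,
                                    n_background=n_background, seed=seed)
    peak_profiles = pbulk_peaks.values                     # groups x peaks
    gene_profiles = pbulk_genes.values                     # groups x genes
    # map original peak column -> position in the (filtered) pseudobulk
    pos = {orig: i for i, orig in enumerate(pbulk_peaks.feature_indices)}
    cl_cols = [pos[i] for i in cluster_peaks if i in pos]
    if not cl_cols:
        raise ValueError("cluster peaks were all dropped in pseudo-bulk")
    rho_cluster = _spearman_matrix(peak_profiles[:, cl_cols], gene_profiles)
    bg_cols = [pos[j] for focal in cluster_peaks if focal in pos
               for j in bg_map[focal] if j in pos]
    rho_bg = _spearman_matrix(peak_profiles[:, bg_cols], gene_profiles)

    n_genes = gene_profiles.shape[1]
    pvals = np.empty(n_genes)
    for j in range(n_genes):
        pvals[j] = mannwhitneyu(rho_cluster[:, j], rho_bg[:, j],
                                alternative="greater").pvalue
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    df = pd.DataFrame({
        "gene": pbulk_genes.feature_indices,
        "mean_rho": rho_cluster.mean(axis=0),
        "bg_rho": rho_bg.mean(axis=0),
        "pvalue": pvals,
        "p_adjusted": p_adj,
    })
    return df.sort_values("mean_rho", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-cell cross-modal states
# ---------------------------------------------------------------------------

def modality_cosine_states(z_teacher_rna: np.ndarray, z_teacher_atac: np.ndarray,
                           distance_cutoff: float = 0.1) -> pd.DataFrame:
    """Per-cell cosine similarity/distance between the paired embeddings.

    Cells with distance above the cutoff are flagged as actively
    transitioning (accessibility and expression disagree).
    """
    a = np.asarray(z_teacher_rna, float)
    b = np.asarray(z_teacher_atac, float)
    if a.shape != b.shape:
        raise ValueError("paired embeddings must share shape")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if (na == 0).any() or (nb == 0).any():
        raise ValueError("zero-norm embedding row")
    sim = np.sum(a * b, axis=1) / (na * nb)
    dist = 1.0 - sim
    return pd.DataFrame({"cosine_sim": sim, "cosine_dist": dist,
                         "flagged": dist > distance_cutoff})


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(expr: np.ndarray, group_labels: np.ndarray,
                            p_adj_cutoff: float = 0.01,
                            logfc_cutoff: float = 0.25,
                            gene_ids: list[str] | None = None) -> pd.DataFrame:
    """One-vs-rest Wilcoxon DEG calls on log-normalized expression.

    log fold change = ln((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1));
    p-values are BH-adjusted within each group; ``significant`` marks rows
    passing both cutoffs. Groups with a single cell are skipped.
    """
    expr = np.asarray(expr, float)
    group_labels = np.asarray(group_labels)
    groups = np.unique(group_labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(expr.shape[1])]
    frames = []
    for grp in groups:
        sel = group_labels == grp
        if sel.sum() < 2:
            warnings.warn(f"group {grp!r} has fewer than 2 cells: skipped")
            continue
        x_in, x_out = expr[sel], expr[~sel]
        res = mannwhitneyu(x_in, x_out, alternative="two-sided", axis=0)
        logfc = np.log((np.expm1(x_in).mean(axis=0) + 1.0)
                       / (np.expm1(x_out).mean(axis=0) + 1.0))
        p_adj = multipletests(res.pvalue, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "group": grp, "gene_id": gene_ids, "logfc": logfc,
            "pvalue": res.pvalue, "p_adjusted": p_adj,
            "significant": (p_adj < p_adj_cutoff) & (logfc > logfc_cutoff),
        }))
    return pd.concat(frames, ignore_index=True)
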