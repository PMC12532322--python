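"""Promoter-interactome truth sets and AUROC evaluation of attention scores.

A PCHi-C-style interaction table (bait interval, other-end interval, one
interaction-confidence score per assayed cell type) is turned into a
binary truth set over the candidate gene-peak pairs: a pair is positive
when the gene TSS lies within ``proximity_bp`` of a bait, the peak lies
within ``proximity_bp`` of that record's other end, and the record's best
score reaches the cutoff. Candidate pairs are all same-chromosome pairs
with |TSS - peak midpoint| <= ``threshold_bp``; boundary comparisons are
inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data_model import GeneAnnotation, PeakInterval
from .decoder import GlobalAttentionMatrix

DEFAULT_THRESHOLD_BP = 1_200_000


@dataclass
class InteractionTruthSet:
    """Binary labels over unique (gene_id, peak_id) pairs with provenance."""

    records: pd.DataFrame            # columns: gene_id, peak_id, label
    n_baited: int = 0
    n_otherend: int = 0
    n_pass_score: int = 0

    def __post_init__(self):
        if self.records.duplicated(["gene_id", "peak_id"]).any():
            raise ValueError("duplicate gene-peak pairs in truth set")
        if not self.records["label"].isin([0, 1]).all():
            raise ValueError("labels must be binary")

    @property
    def positives(self) -> set:
        pos = self.records[self.records["label"] == 1]
        return set(zip(pos["gene_id"], pos["peak_id"]))


def candidate_pairs(genes: list[GeneAnnotation], peaks: list[PeakInterval],
                    threshold_bp: int = DEFAULT_THRESHOLD_BP) -> list[tuple[str, str]]:
    """All same-chromosome pairs with |TSS - midpoint| <= threshold (inclusive)."""
    out = []
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.midpoint, p.peak_id))
    for g in genes:
        for mid, pid in by_chrom.get(g.chrom, ()):
            if abs(g.tss - mid) <= threshold_bp:
                out.append((g.gene_id, pid))
    return out


def _interval_distance(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap between two half-open intervals (0 when they overlap or touch)."""
    if start_a < end_b and start_b < end_a:
        return 0
    return max(start_b - end_a, start_a - end_b, 0)


def read_pchic_table(path: str | Path) -> pd.DataFrame:
    """Read a PCHi-C-like TSV: bait_chrom/start/end, oe_chrom/start/end,
    then one score column per cell type."""
    df = pd.read_csv(path, sep="\t")
    required = ["bait_chrom", "bait_start", "bait_end",
                "oe_chrom", "oe_start", "oe_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"PCHi-C table missing columns: {missing}")
    return df


def build_truth_set(pchic: pd.DataFrame | str | Path,
                    genes: list[GeneAnnotation], peaks: list[PeakInterval],
                    score_cutoff: float = 5.0, proximity_bp: int = 1000,
                    threshold_bp: int = DEFAULT_THRESHOLD_BP) -> InteractionTruthSet:
    """Label candidate pairs against PCHi-C-supported interactions.

    Positive: gene TSS within ``proximity_bp`` of a bait AND peak within
    ``proximity_bp`` of that record's other end AND max score across cell
    types >= ``score_cutoff``. Every other candidate pair is a negative.
    """
    if not isinstance(pchic, pd.DataFrame):
        pchic = read_pchic_table(pchic)
    score_cols = [c for c in pchic.columns
                  if c not in ("bait_chrom", "bait_start", "bait_end",
                               "oe_chrom", "oe_start", "oe_end")]
    if not score_cols:
        raise ValueError("PCHi-C table has no score columns")
    pchic_chroms = set(pchic["bait_chrom"]) | set(pchic["oe_chrom"])
    feat_chroms = {g.chrom for g in genes} | {p.chrom for p in peaks}
    if not pchic_chroms & feat_chroms:
        raise ValueError("no chromosome names shared between PCHi-C table and "
                         "features; inputs must be on one assembly")

    passing = pchic[pchic[score_cols].max(axis=1) >= score_cutoff]
    n_baited = n_otherend = 0
    positives: set[tuple[str, str]] = set()
    for row in passing.itertuples(index=False):
        near_genes = [g for g in genes
                      if g.chrom == row.bait_chrom and _interval_distance(
                          g.tss, g.tss + 1, row.bait_start, row.bait_end) <= proximity_bp]
        near_peaks = [p for p in peaks
                      if p.chrom == row.oe_chrom and _interval_distance(
                          p.start, p.end, row.oe_start, row.oe_end) <= proximity_bp]
        n_baited += bool(near_genes)
        n_otherend += bool(near_peaks)
        for g in near_genes:
            for p in near_peaks:
                positives.add((g.gene_id, p.peak_id))

    cands = candidate_pairs(genes, peaks, threshold_bp)
    positives &= set(cands)
    if not positives:
        import warnings
        warnings.warn("truth set has no positive pairs")
    records = pd.DataFrame({
        "gene_id": [g for g, _ in cands],
        "peak_id": [p for _, p in cands],
        "label": [1 if pair in positives else 0 for pair in cands],
    })
    return InteractionTruthSet(records=records, n_baited=n_baited,
                               n_otherend=n_otherend, n_pass_score=len(passing))


def auroc(scores: dict | GlobalAttentionMatrix, truth: InteractionTruthSet) -> float:
    """Rank-based AUROC (midrank tie handling) of pair scores vs truth labels."""
    if isinstance(scores, GlobalAttentionMatrix):
        pairs = scores.to_pairs()
        scores = dict(zip(zip(pairs["gene_id"], pairs["peak_id"]), pairs["weight"]))
    labels = truth.records["label"].to_numpy()
    if labels.min() == labels.max():
        raise ValueError("AUROC undefined: single-class truth set")
    vals = np.array([scores.get((g, p), 0.0) for g, p in
                     zip(truth.records["gene_id"], truth.records["peak_id"])])
    return float(roc_auc_score(labels, vals))


# ---------------------------------------------------------------------------
# top-pair selection and dense peak-associated genes
# ---------------------------------------------------------------------------

def kneedle_elbow(y: np.ndarray) -> int:
    """Index of maximum deviation from the endpoint chord of a sorted curve."""
    y = np.asarray(y, float)
    if y.size < 3:
        return 0
    x = np.linspace(0.0, 1.0, y.size)
    span = y[-1] - y[0]
    yn = (y - y[0]) / span if span != 0 else np.zeros_like(y)
    chord = x * (yn[-1] - yn[0]) + yn[0]
    return int(np.argmax(np.abs(yn - chord)))


def select_top_attention(global_attn: GlobalAttentionMatrix, frac: float = 0.10,
                         method: str = "quantile") -> list[tuple[str, str]]:
    """Top-weighted unmasked gene-peak pairs.

    ``quantile``: top ceil(frac * n) pairs by weight, ties broken by
    (gene_id, peak_id) lexicographic order; ``elbow``: all pairs above the
    kneedle point of the sorted-weight curve.
    """
    pairs = global_attn.to_pairs()
    if pairs.empty:
        raise ValueError("no unmasked pairs to select from")
    pairs = pairs.sort_values(["weight", "gene_id", "peak_id"],
                              ascending=[False, True, True], kind="mergesort")
    if method == "quantile":
        n_sel = int(np.ceil(frac * len(pairs)))
    elif method == "elbow":
        n_sel = kneedle_elbow(pairs["weight"].to_numpy()) + 1
    else:
        raise ValueError(f"unknown method {method!r}")
    head = pairs.head(n_sel)
    return list(zip(head["gene_id"], head["peak_id"]))


def dense_peak_associated_genes(selected_pairs: list[tuple[str, str]],
                                min_peaks: int = 10) -> set[str]:
    """Genes linked to at least ``min_peaks`` distinct selected peaks."""
    per_gene: dict[str, set] = {}
    for g, p in selected_pairs:
        per_gene.setdefault(g, set()).add(p)
    return {g for g, ps in per_gene.items() if len(ps) >= min_peaks}
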