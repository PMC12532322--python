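"""Synthetic paired multiome generator with planted structure.

Cells lie on a pseudotime trajectory partitioned into cell types; each
type has a Gaussian activity program along pseudotime. Linked peaks read
their program's activity (shared per-cell lognormal noise), and each
linked gene reads the *same* per-cell activity realization as its peaks
— except lag genes, which read the program at pseudotime t - lag_shift
with an independent noise realization, emulating chromatin accessibility
leading transcription. Counts are Poisson draws from these rates. Decoy
peaks carry unstructured lognormal noise. Genomic coordinates place each
gene in its own 3-Mb locus with its linked peaks and decoys within 1.1 Mb
of the TSS (inside the 1.2-Mb attention window), on a 2.5-kb offset grid
so that no two peaks of a locus collide during truth-set matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import CellMeta, GeneAnnotation, MultiomeDataset, PeakInterval

LOCUS_SPACING = 3_000_000
LOCUS_BASE = 1_200_000
MAX_OFFSET = 1_100_000
OFFSET_GRID = 2_500
PEAK_WIDTH = 500


@dataclass
class SimulationTruth:
    """Ground truth planted by :func:`generate_multiome`."""

    cell_type: list[str]
    pseudotime: np.ndarray
    planted_links: list[tuple[str, str, float]]
    lag_genes: list[str]
    lag_shift: float
    program_of_gene: dict[str, int]
    program_of_peak: dict[str, int]
    peak_gc: np.ndarray
    genes: list[GeneAnnotation] = field(default_factory=list)
    peaks: list[PeakInterval] = field(default_factory=list)

    @property
    def linked_pairs(self) -> set[tuple[str, str]]:
        return {(g, p) for g, p, _ in self.planted_links}


def _program_activity(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((t - center) ** 2) / (2.0 * width ** 2))


def generate_multiome(n_cells: int = 600, n_genes: int = 300, n_peaks: int = 600,
                      n_types: int = 3, n_links_per_gene: int = 2,
                      lag_frac: float = 0.5, noise: float = 0.3, seed: int = 0,
                      linked_gene_frac: float = 2.0 / 3.0,
                      lag_shift: float = 0.15,
                      baseline: float = 0.1):
    """Simulate a paired multiome dataset with planted regulatory links.

    Returns (MultiomeDataset, SimulationTruth); bit-reproducible for a
    fixed seed. ``noise`` is the s.d. of the shared per-cell lognormal
    activity noise; ``lag_frac`` is the fraction of linked genes whose
    expression lags accessibility by ``lag_shift`` pseudotime units.
    """
    if min(n_cells, n_genes, n_peaks, n_types, n_links_per_gene) <= 0:
        raise ValueError("all size arguments must be positive")
    n_linked_genes = int(round(linked_gene_frac * n_genes))
    n_linked_peaks = n_linked_genes * n_links_per_gene
    if n_linked_peaks > n_peaks:
        raise ValueError(
            f"infeasible link budget: {n_linked_genes} linked genes x "
            f"{n_links_per_gene} peaks > {n_peaks} peaks")
    rng = np.random.default_rng(seed)

    # trajectory, types, program activities
    t = rng.uniform(0.0, 1.0, size=n_cells)
    type_idx = np.minimum((t * n_types).astype(int), n_types - 1)
    cell_type = [f"type{k}" for k in type_idx]
    centers = (np.arange(n_types) + 0.5) / n_types
    width = 0.6 / n_types

    def lognorm(shape):
        return np.exp(noise * rng.standard_normal(shape) - 0.5 * noise ** 2) \
            if noise > 0 else np.ones(shape)

    f_now = np.stack([_program_activity(t, c, width) for c in centers])        # K x N
    f_lag = np.stack([_program_activity(t - lag_shift, c, width) for c in centers])
    act_now = f_now * lognorm((n_types, n_cells))      # shared by peaks & prompt genes
    act_lag = f_lag * lognorm((n_types, n_cells))      # independent realization

    # gene annotations on a fixed locus grid over 4 autosomes
    genes = []
    for g in range(n_genes):
        chrom = f"chr{(g % 4) + 1}"
        tss = LOCUS_BASE + LOCUS_SPACING * (g // 4)
        genes.append(GeneAnnotation(gene_id=f"gene{g:04d}", symbol=f"gene{g:04d}",
                                    chrom=chrom, tss=tss,
                                    strand="+" if g % 2 == 0 else "-"))

    # assign peaks to loci: linked peaks to their gene, decoys round-robin
    gene_program = {genes[g].gene_id: g % n_types for g in range(n_linked_genes)}
    n_decoys = n_peaks - n_linked_peaks
    decoy_host = [g % n_genes for g in range(n_decoys)]
    peaks_per_locus: dict[int, int] = {}
    for g in range(n_linked_genes):
        peaks_per_locus[g] = n_links_per_gene
    for g in decoy_host:
        peaks_per_locus[g] = peaks_per_locus.get(g, 0) + 1

    offsets_grid = np.concatenate([
        np.arange(-MAX_OFFSET, -OFFSET_GRID + 1, OFFSET_GRID),
        np.arange(OFFSET_GRID, MAX_OFFSET + 1, OFFSET_GRID)])
    peak_rows = []       # (PeakInterval, program or -1, host gene index)
    for g, count in sorted(peaks_per_locus.items()):
        offs = rng.choice(offsets_grid, size=count, replace=False)
        n_link_here = n_links_per_gene if g < n_linked_genes else 0
        for j, off in enumerate(offs):
            center = genes[g].tss + int(off)
            peak = PeakInterval(chrom=genes[g].chrom,
                                start=center - PEAK_WIDTH // 2,
                                end=center + PEAK_WIDTH // 2)
            program = gene_program[genes[g].gene_id] if j < n_link_here else -1
            peak_rows.append((peak, program, g))
    order = rng.permutation(len(peak_rows))
    peak_rows = [peak_rows[i] for i in order]
    peaks = [row[0] for row in peak_rows]

    # rates and counts
    atac_rate = np.empty((n_cells, n_peaks))
    for j, (peak, program, host) in enumerate(peak_rows):
        depth = rng.uniform(1.0, 2.0)
        amp = rng.uniform(0.8, 1.2)
        if program >= 0:
            activity = amp * act_now[program]
        else:
            activity = 0.4 * lognorm(n_cells)
        atac_rate[:, j] = depth * (baseline + activity)
    atac_counts = rng.poisson(atac_rate)

    lag_pool = [genes[g].gene_id for g in range(n_linked_genes)]
    n_lag = int(round(lag_frac * n_linked_genes))
    lag_genes = sorted(rng.choice(lag_pool, size=n_lag, replace=False).tolist())
    lag_set = set(lag_genes)
    rna_rate = np.empty((n_cells, n_genes))
    gene_amp = {}
    for g in range(n_genes):
        gid = genes[g].gene_id
        depth = rng.uniform(2.0, 4.0)
        amp = rng.uniform(0.8, 1.2)
        gene_amp[gid] = amp
        if gid in gene_program:
            source = act_lag if gid in lag_set else act_now
            activity = amp * source[gene_program[gid]]
        else:
            activity = 0.4 * lognorm(n_cells)
        rna_rate[:, g] = depth * (baseline + activity)
    rna_counts = rng.poisson(rna_rate)

    planted = []
    for peak, program, host in peak_rows:
        if program >= 0:
            gid = genes[host].gene_id
            planted.append((gid, peak.peak_id, gene_amp[gid]))
    program_of_peak = {peak.peak_id: program for peak, program, _ in peak_rows}
    peak_gc = rng.uniform(0.3, 0.7, size=n_peaks)

    cells = [CellMeta(barcode=f"cell{i:04d}", cell_type=cell_type[i],
                      pseudotime=float(t[i])) for i in range(n_cells)]
    dataset = MultiomeDataset(sp.csr_matrix(rna_counts), sp.csr_matrix(atac_counts),
                              genes, peaks, cells)
    truth = SimulationTruth(cell_type=cell_type, pseudotime=t,
                            planted_links=planted, lag_genes=lag_genes,
                            lag_shift=lag_shift,
                            program_of_gene=dict(gene_program),
                            program_of_peak=program_of_peak,
                            peak_gc=peak_gc, genes=genes, peaks=peaks)
    return dataset, truth


def generate_pchic_like(truth: SimulationTruth, fp_rate: float = 0.1,
                        seed: int = 0) -> pd.DataFrame:
    """Emulate a PCHi-C interaction table from the planted links.

    Each planted link becomes a row: bait = TSS +/- 500 bp, other end =
    the peak padded by 200 bp, score >= 5 in the program's cell-type
    column and < 5 elsewhere. A ``fp_rate`` fraction of decoy rows is
    added: half re-list real anchors with all scores < 5, half place
    high-scoring baits between loci where no gene lies. Row order is
    shuffled.
    """
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in truth.genes}
    peak_by_id = {p.peak_id: p for p in truth.peaks}
    n_types = max(truth.program_of_gene.values(), default=0) + 1
    score_cols = [f"score_type{k}" for k in range(n_types)]
    rows = []

    def make_row(gene, peak, scores):
        return {"bait_chrom": gene.chrom, "bait_start": gene.tss - 500,
                "bait_end": gene.tss + 500, "oe_chrom": peak.chrom,
                "oe_start": peak.start - 200, "oe_end": peak.end + 200,
                **dict(zip(score_cols, scores))}

    for gid, pid, _ in truth.planted_links:
        gene, peak = gene_by_id[gid], peak_by_id[pid]
        program = truth.program_of_gene[gid]
        scores = rng.uniform(0.0, 4.0, size=n_types)
        scores[program] = rng.uniform(6.0, 14.0)
        rows.append(make_row(gene, peak, scores))

    n_decoy = int(round(fp_rate * len(truth.planted_links)))
    link_idx = rng.integers(0, len(truth.planted_links), size=n_decoy)
    for i, li in enumerate(link_idx):
        gid, pid, _ = truth.planted_links[li]
        gene, peak = gene_by_id[gid], peak_by_id[pid]
        if i % 2 == 0:      # real anchors, sub-threshold scores
            rows.append(make_row(gene, peak, rng.uniform(0.0, 4.9, size=n_types)))
        else:               # high score, bait in a gene desert between loci
            shift = LOCUS_SPACING // 2
            fake = GeneAnnotation(gene_id="na", symbol="na", chrom=gene.chrom,
                                  tss=gene.tss + shift, strand="+")
            scores = rng.uniform(6.0, 14.0, size=n_types)
            rows.append(make_row(fake, peak, scores))

    df = pd.DataFrame(rows)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def sparsity_report(dataset: MultiomeDataset) -> dict:
    """Fraction of zero entries per modality (generation-time sanity)."""
    def frac_zero(m):
        return 1.0 - m.nnz / (m.shape[0] * m.shape[1])
    return {"rna": frac_zero(dataset.rna_counts),
            "atac": frac_zero(dataset.atac_counts)}
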