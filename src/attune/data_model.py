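"""Domain types, I/O, and preprocessing for paired multiome data.

Conventions: genomic intervals are 0-based half-open (BED); GTF input is
converted on read (1-based, inclusive -> 0-based half-open); the TSS of a
'+' gene is its start and of a '-' gene its end-1. Counts are raw
nonnegative integers until :func:`normalize_log`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})
TARGET_LIBRARY_SIZE = 10_000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/- for {self.gene_id}")


@dataclass(frozen=True)
class PeakInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid peak interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CellMeta:
    barcode: str
    cell_type: str | None = None
    pseudotime: float | None = None


@dataclass
class MultiomeDataset:
    """Row-aligned paired cell x gene and cell x peak raw count matrices."""

    rna_counts: sp.csr_matrix
    atac_counts: sp.csr_matrix
    genes: list[GeneAnnotation]
    peaks: list[PeakInterval]
    cells: list[CellMeta]
    paired: bool = True

    def __post_init__(self):
        self.rna_counts = sp.csr_matrix(self.rna_counts)
        self.atac_counts = sp.csr_matrix(self.atac_counts)
        if self.rna_counts.shape[0] != self.atac_counts.shape[0]:
            raise ValueError("modalities have different cell counts")
        if self.rna_counts.shape[1] != len(self.genes):
            raise ValueError("gene annotation length != RNA columns")
        if self.atac_counts.shape[1] != len(self.peaks):
            raise ValueError("peak annotation length != ATAC columns")
        if len(self.cells) != self.rna_counts.shape[0]:
            raise ValueError("cell metadata length != rows")
        barcodes = [c.barcode for c in self.cells]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes")
        for m, name in ((self.rna_counts, "RNA"), (self.atac_counts, "ATAC")):
            _validate_raw_counts(m, name)

    @property
    def n_cells(self) -> int:
        return self.rna_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.rna_counts.shape[1]

    @property
    def n_peaks(self) -> int:
        return self.atac_counts.shape[1]


def _validate_raw_counts(m: sp.spmatrix, name: str) -> None:
    data = m.data if sp.issparse(m) else np.asarray(m).ravel()
    if data.size and data.min() < 0:
        raise ValueError(f"{name} counts contain negative entries")
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError(f"{name} counts contain non-integral entries")


@dataclass
class EncodedCellBatch:
    """Per-cell sparse (index, value) arrays for both modalities.

    Indices are strictly increasing within each cell; zero entries are
    omitted. ``n_genes``/``n_peaks`` give the full feature-space widths.
    """

    gene_indices: list[np.ndarray]
    gene_values: list[np.ndarray]
    peak_indices: list[np.ndarray]
    peak_values: list[np.ndarray]
    n_genes: int
    n_peaks: int

    def __post_init__(self):
        n = len(self.gene_indices)
        if not (len(self.gene_values) == len(self.peak_indices)
                == len(self.peak_values) == n):
            raise ValueError("ragged batch: per-cell list lengths differ")
        for idxs, vals, width, label in (
            (self.gene_indices, self.gene_values, self.n_genes, "gene"),
            (self.peak_indices, self.peak_values, self.n_peaks, "peak"),
        ):
            for i, v in zip(idxs, vals):
                if len(i) != len(v):
                    raise ValueError(f"{label} index/value length mismatch")
                if len(i) and (i.min() < 0 or i.max() >= width):
                    raise ValueError(f"{label} index out of range")
                if len(i) > 1 and not np.all(np.diff(i) > 0):
                    raise ValueError(f"{label} indices not strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.gene_indices)

    def to_dense(self, modality: str) -> np.ndarray:
        if modality == "RNA":
            idxs, vals, width = self.gene_indices, self.gene_values, self.n_genes
        elif modality == "ATAC":
            idxs, vals, width = self.peak_indices, self.peak_values, self.n_peaks
        else:
            raise ValueError(f"unknown modality {modality!r}")
        out = np.zeros((self.n_cells, width))
        for row, (i, v) in enumerate(zip(idxs, vals)):
            out[row, i] = v
        return out

    def subset(self, rows: np.ndarray) -> "EncodedCellBatch":
        rows = np.asarray(rows)
        return EncodedCellBatch(
            [self.gene_indices[r] for r in rows],
            [self.gene_values[r] for r in rows],
            [self.peak_indices[r] for r in rows],
            [self.peak_values[r] for r in rows],
            self.n_genes, self.n_peaks,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from a 4/5-column TSV or a GTF file.

    TSV columns: gene_id, chrom, tss, strand[, symbol] (header optional,
    detected by a non-numeric third field on line one). GTF 'gene'
    records are converted from 1-based inclusive to a 0-based TSS.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf_genes(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    first = df.iloc[0]
    try:
        int(first[2])
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    genes = []
    for row in df.itertuples(index=False):
        symbol = row[4] if len(row) > 4 and isinstance(row[4], str) else row[0]
        genes.append(GeneAnnotation(gene_id=row[0], symbol=symbol, chrom=row[1],
                                    tss=int(row[2]), strand=row[3]))
    return genes


def _read_gtf_genes(path: Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = {}
            for item in f[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            start0 = int(f[3]) - 1          # GTF is 1-based inclusive
            end0 = int(f[4])                # exclusive end in 0-based terms
            strand = f[6]
            tss = start0 if strand == "+" else end0 - 1
            gid = attrs.get("gene_id", f"{f[0]}:{start0}")
            genes.append(GeneAnnotation(gene_id=gid,
                                        symbol=attrs.get("gene_name", gid),
                                        chrom=f[0], tss=tss, strand=strand))
    return genes


def read_peaks_bed(path: str | Path) -> list[PeakInterval]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return [PeakInterval(chrom=r[0], start=int(r[1]), end=int(r[2]))
            for r in df.itertuples(index=False)]


def write_peaks_bed(peaks: list[PeakInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_cell_metadata(path: str | Path) -> list[CellMeta]:
    df = pd.read_csv(path, sep="\t")
    cells = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pt = d.get("pseudotime")
        cells.append(CellMeta(
            barcode=str(d["barcode"]),
            cell_type=str(d["cell_type"]) if "cell_type" in d and pd.notna(d["cell_type"]) else None,
            pseudotime=float(pt) if pt is not None and pd.notna(pt) else None,
        ))
    return cells


def _read_mtx_dir(directory: str | Path):
    directory = Path(directory)
    try:
        matrix = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx"))
    except ValueError as exc:
        raise ValueError(f"malformed MTX file in {directory}: {exc}") from exc
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    # MTX convention: features x cells -> transpose to cells x features
    if matrix.shape == (len(features), len(barcodes)):
        matrix = sp.csr_matrix(matrix.T)
    if matrix.shape != (len(barcodes), len(features)):
        raise ValueError(f"matrix shape {matrix.shape} inconsistent with "
                         f"{len(barcodes)} barcodes / {len(features)} features in {directory}")
    return matrix, barcodes, features


def read_mtx_dataset(rna_dir, atac_dir, genes, peaks, cells=None) -> MultiomeDataset:
    """Assemble a row-aligned :class:`MultiomeDataset` from MTX triplet dirs.

    Barcodes present in only one modality are dropped with a warning;
    rows follow the RNA barcode order restricted to the intersection.
    """
    rna, rna_bc, rna_feats = _read_mtx_dir(rna_dir)
    atac, atac_bc, atac_feats = _read_mtx_dir(atac_dir)
    common = set(rna_bc) & set(atac_bc)
    if not common:
        raise ValueError("no shared barcodes between RNA and ATAC: pairing failed")
    if len(common) < max(len(rna_bc), len(atac_bc)):
        warnings.warn(
            f"barcode mismatch: keeping {len(common)} shared cells "
            f"(RNA {len(rna_bc)}, ATAC {len(atac_bc)})")
    order = [bc for bc in rna_bc if bc in common]
    rna_pos = {bc: i for i, bc in enumerate(rna_bc)}
    atac_pos = {bc: i for i, bc in enumerate(atac_bc)}
    rna = rna[[rna_pos[bc] for bc in order], :]
    atac = atac[[atac_pos[bc] for bc in order], :]

    gene_ann = read_gene_annotations(genes)
    gene_by_id = {g.gene_id: g for g in gene_ann}
    gene_list = [gene_by_id[g] for g in rna_feats]
    peak_list = read_peaks_bed(peaks)
    if cells is not None:
        meta = {c.barcode: c for c in read_cell_metadata(cells)}
        cell_list = [meta.get(bc, CellMeta(barcode=bc)) for bc in order]
    else:
        cell_list = [CellMeta(barcode=bc) for bc in order]
    return MultiomeDataset(rna, atac, gene_list, peak_list, cell_list)


def write_mtx_dataset(dataset: MultiomeDataset, rna_dir, atac_dir,
                      genes_path, peaks_path, cells_path) -> None:
    """Inverse of :func:`read_mtx_dataset` (feature-major MTX orientation)."""
    for directory, matrix, feats in (
        (Path(rna_dir), dataset.rna_counts, [g.gene_id for g in dataset.genes]),
        (Path(atac_dir), dataset.atac_counts, [p.peak_id for p in dataset.peaks]),
    ):
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(matrix.T))
        pd.Series([c.barcode for c in dataset.cells]).to_csv(
            directory / "barcodes.tsv", sep="\t", header=False, index=False)
        pd.Series(feats).to_csv(directory / "features.tsv", sep="\t",
                                header=False, index=False)
    with open(genes_path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tsymbol\n")
        for g in dataset.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.symbol}\n")
    write_peaks_bed(dataset.peaks, peaks_path)
    with open(cells_path, "w") as fh:
        fh.write("barcode\tcell_type\tpseudotime\n")
        for c in dataset.cells:
            ct = c.cell_type if c.cell_type is not None else ""
            pt = c.pseudotime if c.pseudotime is not None else ""
            fh.write(f"{c.barcode}\t{ct}\t{pt}\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_features(counts, min_cell_frac: float = 0.05):
    """Keep features nonzero in at least ceil(min_cell_frac * N) cells.

    Returns (filtered matrix, kept column indices); column order preserved.
    """
    if not 0.0 <= min_cell_frac <= 1.0:
        raise ValueError("min_cell_frac must be in [0, 1]")
    m = sp.csc_matrix(counts) if sp.issparse(counts) else np.asarray(counts)
    n = m.shape[0]
    nnz = (m != 0).sum(axis=0)
    nnz = np.asarray(nnz).ravel()
    threshold = math.ceil(min_cell_frac * n)
    kept = np.flatnonzero(nnz >= threshold)
    if kept.size == 0:
        raise ValueError(f"no features survive filtering at min_cell_frac={min_cell_frac}")
    out = m[:, kept]
    if sp.issparse(out):
        out = sp.csr_matrix(out)
    return out, kept


def normalize_log(counts):
    """Scale each cell to 10,000 total counts, then log1p.

    All-zero cells stay all-zero (with a warning) rather than being dropped.
    """
    dense_in = not sp.issparse(counts)
    m = sp.csr_matrix(np.asarray(counts, dtype=np.float64)) if dense_in \
        else sp.csr_matrix(counts, dtype=np.float64, copy=True)
    if m.data.size and m.data.min() < 0:
        raise ValueError("negative entries in count matrix")
    totals = np.asarray(m.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell(s) left unnormalized")
    scale = np.where(zero, 0.0, TARGET_LIBRARY_SIZE / np.where(zero, 1.0, totals))
    m = sp.csr_matrix(sp.diags(scale) @ m)
    m = m.log1p()
    return m.toarray() if dense_in else m


def select_hvg(normalized, n_top: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Rank genes by mean-binned normalized dispersion (Seurat-v1 style).

    Operates on log1p-normalized expression: per-gene mean and dispersion
    (variance/mean) are computed on the expm1 scale, dispersions are
    z-scored within ``n_bins`` mean bins, and the ``n_top`` genes with the
    largest normalized dispersion are returned as sorted column indices.
    Ties break toward the lower gene index.
    """
    x = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)
    n_genes = x.shape[1]
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {n_genes}")
    counts = np.expm1(x)
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, np.nan)
    dispersion[dispersion == 0] = np.nan
    dispersion = np.log(dispersion)
    log_mean = np.log1p(mean)

    df = pd.DataFrame({"mean": log_mean, "disp": dispersion})
    df["bin"] = pd.cut(df["mean"], bins=n_bins)
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_mean = grouped.mean()
    bin_std = grouped.std(ddof=1)
    singleton = bin_std.isna()
    bin_std[singleton] = bin_mean[singleton].abs()
    bin_mean[singleton] = 0.0
    mu = df["bin"].map(bin_mean).to_numpy(dtype=float)
    sd = df["bin"].map(bin_std).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_disp = (dispersion - mu) / sd
    norm_disp = np.where(np.isfinite(norm_disp), norm_disp, -np.inf)
    order = np.argsort(-norm_disp, kind="stable")  # ties -> lower index first
    return np.sort(order[:n_top])


def remove_sex_chromosomes(features, sex_chroms=SEX_CHROMOSOMES):
    """Drop features annotated on sex chromosomes.

    Returns (kept feature list, kept indices).
    """
    kept = [i for i, f in enumerate(features) if f.chrom not in sex_chroms]
    return [features[i] for i in kept], np.asarray(kept, dtype=int)


def encode_cells(normalized_rna, normalized_atac) -> EncodedCellBatch:
    """Sparsify row-aligned normalized matrices into per-cell index/value arrays."""
    rna = sp.csr_matrix(normalized_rna)
    atac = sp.csr_matrix(normalized_atac)
    if rna.shape[0] != atac.shape[0]:
        raise ValueError("modalities not row-aligned")
    rna.sort_indices()
    atac.sort_indices()

    def per_cell(m):
        idxs, vals = [], []
        for i in range(m.shape[0]):
            lo, hi = m.indptr[i], m.indptr[i + 1]
            idxs.append(m.indices[lo:hi].astype(np.int64))
            vals.append(m.data[lo:hi].astype(np.float64))
        return idxs, vals

    gi, gv = per_cell(rna)
    pi, pv = per_cell(atac)
    return EncodedCellBatch(gi, gv, pi, pv, rna.shape[1], atac.shape[1])


@dataclass
class ProcessedData:
    """Output of the preprocessing pipeline feeding the encoders."""

    batch: EncodedCellBatch
    genes: list[GeneAnnotation]
    peaks: list[PeakInterval]
    cells: list[CellMeta]
    rna_norm: np.ndarray = field(repr=False, default=None)
    atac_norm: np.ndarray = field(repr=False, default=None)


def preprocess(dataset: MultiomeDataset, min_cell_frac: float = 0.05,
               n_top_hvg: int | None = 2000, drop_sex: bool = True) -> ProcessedData:
    """Standard pipeline: feature filter -> sex-chromosome removal ->
    per-cell normalization/log1p -> HVG selection -> sparse encoding."""
    rna, gkept = filter_features(dataset.rna_counts, min_cell_frac)
    atac, pkept = filter_features(dataset.atac_counts, min_cell_frac)
    genes = [dataset.genes[i] for i in gkept]
    peaks = [dataset.peaks[i] for i in pkept]
    if drop_sex:
        genes, gk2 = remove_sex_chromosomes(genes)
        peaks, pk2 = remove_sex_chromosomes(peaks)
        rna, atac = rna[:, gk2], atac[:, pk2]
    rna_n = normalize_log(rna)
    atac_n = normalize_log(atac)
    rna_n = rna_n.toarray() if sp.issparse(rna_n) else rna_n
    atac_n = atac_n.toarray() if sp.issparse(atac_n) else atac_n
    if n_top_hvg is not None and n_top_hvg < rna_n.shape[1]:
        hvg = select_hvg(rna_n, n_top=n_top_hvg)
        rna_n = rna_n[:, hvg]
        genes = [genes[i] for i in hvg]
    batch = encode_cells(rna_n, atac_n)
    return ProcessedData(batch=batch, genes=genes, peaks=peaks,
                         cells=list(dataset.cells), rna_norm=rna_n, atac_norm=atac_n)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_processed(proc: ProcessedData, path: str | Path) -> None:
    """Write a :class:`ProcessedData` to an HDF5 container.

    Layout: per-modality ragged (indices, values, offsets) datasets plus
    gene/peak/cell annotation tables as fixed string arrays.
    """
    with h5py.File(path, "w") as f:
        for name, idxs, vals, width in (
            ("rna", proc.batch.gene_indices, proc.batch.gene_values, proc.batch.n_genes),
            ("atac", proc.batch.peak_indices, proc.batch.peak_values, proc.batch.n_peaks),
        ):
            grp = f.create_group(name)
            offsets = np.cumsum([0] + [len(i) for i in idxs])
            grp.create_dataset("indices", data=np.concatenate(idxs) if offsets[-1] else np.empty(0, int))
            grp.create_dataset("values", data=np.concatenate(vals) if offsets[-1] else np.empty(0))
            grp.create_dataset("offsets", data=offsets)
            grp.attrs["n_features"] = width
        f.create_dataset("genes", data=np.array(
            [[g.gene_id, g.symbol, g.chrom, str(g.tss), g.strand] for g in proc.genes],
            dtype=h5py.string_dtype()))
        f.create_dataset("peaks", data=np.array(
            [[p.chrom, str(p.start), str(p.end)] for p in proc.peaks],
            dtype=h5py.string_dtype()))
        f.create_dataset("cells", data=np.array(
            [[c.barcode, c.cell_type or "", "" if c.pseudotime is None else repr(c.pseudotime)]
             for c in proc.cells], dtype=h5py.string_dtype()))


def load_processed(path: str | Path) -> ProcessedData:
    with h5py.File(path, "r") as f:
        def ragged(name):
            grp = f[name]
            offsets = grp["offsets"][:]
            indices = grp["indices"][:]
            values = grp["values"][:]
            idxs = [indices[lo:hi] for lo, hi in zip(offsets[:-1], offsets[1:])]
            vals = [values[lo:hi] for lo, hi in zip(offsets[:-1], offsets[1:])]
            return idxs, vals, int(grp.attrs["n_features"])

        gi, gv, ng = ragged("rna")
        pi, pv, np_ = ragged("atac")
        genes = [GeneAnnotation(gene_id=r[0].decode(), symbol=r[1].decode(),
                                chrom=r[2].decode(), tss=int(r[3]), strand=r[4].decode())
                 for r in f["genes"][:]]
        peaks = [PeakInterval(chrom=r[0].decode(), start=int(r[1]), end=int(r[2]))
                 for r in f["peaks"][:]]
        cells = [CellMeta(barcode=r[0].decode(),
                          cell_type=r[1].decode() or None,
                          pseudotime=float(r[2]) if r[2] else None)
                 for r in f["cells"][:]]
    batch = EncodedCellBatch(gi, gv, pi, pv, ng, np_)
    proc = ProcessedData(batch=batch, genes=genes, peaks=peaks, cells=cells)
    proc.rna_norm = batch.to_dense("RNA")
    proc.atac_norm = batch.to_dense("ATAC")
    return proc
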