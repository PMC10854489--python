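"""Peak-level quantification: per-cell counting, cluster aggregation (CPM)
and the two peak filters (low-count CPM filter, A-rich internal-priming
filter).

A read is assigned to the unique peak of its gene that contains its
strand-aware 3' terminus — the same coordinate the peak caller counts — so
counting and calling agree about what a "read in a peak" means. Internal
priming (oligo-dT annealing to genomic A-stretches rather than the polyA
tail) leaves an A-rich run immediately 3' of the apparent cleavage site;
peaks whose downstream window is A-rich on the read strand are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .alignments import TaggedAlignment
from .peaks import Peak

logger = logging.getLogger(__name__)

__all__ = [
    "PeakCounts",
    "ClusterCounts",
    "count_reads_in_peaks",
    "aggregate_by_cluster",
    "cpm_filter",
    "a_rich_filter",
    "subset_peak_counts",
    "drop_single_peak_genes",
    "write_mtx_triplet",
]


@dataclass
class PeakCounts:
    """Sparse peak x cell UMI count matrix with peak and cell metadata."""

    peaks: list[Peak]
    barcodes: list[str]
    matrix: sp.csr_matrix  # peaks x cells, non-negative ints
    cluster_of: dict[str, str]
    unassigned: int = 0

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.peaks), len(self.barcodes)):
            raise ValueError("matrix shape inconsistent with peak/cell lists")
        missing = [bc for bc in self.barcodes if bc not in self.cluster_of]
        if missing:
            raise ValueError(f"{len(missing)} barcodes lack a cluster label")

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]


@dataclass
class ClusterCounts:
    """Peak x cluster count sums and their per-cluster CPM normalisation."""

    peaks: list[Peak]
    clusters: list[str]
    matrix: np.ndarray  # peak x cluster counts
    cpm: np.ndarray  # counts * 1e6 / cluster total (zero column where total 0)

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def gene_table(self, gene_id: str, clusters: Sequence[str] | None = None) -> np.ndarray:
        """Counts of the gene's peaks (rows, in order_index order) across the
        requested clusters (columns)."""
        rows = [i for i, p in enumerate(self.peaks) if p.gene_id == gene_id]
        rows.sort(key=lambda i: self.peaks[i].order_index or 0)
        cols = (
            list(range(len(self.clusters)))
            if clusters is None
            else [self.clusters.index(c) for c in clusters]
        )
        return self.matrix[np.ix_(rows, cols)]


def count_reads_in_peaks(
    reads: Iterable[TaggedAlignment],
    peaks: Sequence[Peak],
    barcodes: Sequence[str],
    cluster_of: Mapping[str, str],
) -> PeakCounts:
    """Count deduplicated reads into peaks per cell.

    A read increments the peak of its own gene whose [start, end) contains
    its strand-aware 3' terminus; peaks of one gene are disjoint so the
    assignment is unique. Reads landing in no peak of their gene are tallied
    as unassigned (assigned + unassigned = input reads).
    """
    peak_row = {p.peak_id: i for i, p in enumerate(peaks)}
    by_gene: dict[str, list[Peak]] = {}
    for p in peaks:
        by_gene.setdefault(p.gene_id, []).append(p)
    col = {bc: j for j, bc in enumerate(barcodes)}
    rows, cols = [], []
    unassigned = 0
    for r in reads:
        if r.gene_id is None or r.barcode not in col:
            unassigned += 1
            continue
        hit = None
        for p in by_gene.get(r.gene_id, ()):
            if p.contains(r.terminus):
                hit = p
                break
        if hit is None:
            unassigned += 1
            continue
        rows.append(peak_row[hit.peak_id])
        cols.append(col[r.barcode])
    data = np.ones(len(rows), dtype=np.int64)
    matrix = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(peaks), len(barcodes))
    ).tocsr()
    matrix.sum_duplicates()
    return PeakCounts(
        peaks=list(peaks), barcodes=list(barcodes), matrix=matrix,
        cluster_of=dict(cluster_of), unassigned=unassigned,
    )


def aggregate_by_cluster(pc: PeakCounts, clusters: Sequence[str] | None = None) -> ClusterCounts:
    """Sum peak x cell counts within clusters and normalise each cluster
    column to counts-per-million (zero columns stay zero, with a warning)."""
    if clusters is None:
        clusters = sorted(set(pc.cluster_of.values()))
    idx = {c: k for k, c in enumerate(clusters)}
    matrix = np.zeros((len(pc.peaks), len(clusters)), dtype=np.int64)
    dense = pc.matrix
    for j, bc in enumerate(pc.barcodes):
        k = idx.get(pc.cluster_of[bc])
        if k is not None:
            matrix[:, k] += np.asarray(dense[:, j].todense()).ravel()
    totals = matrix.sum(axis=0)
    cpm = np.zeros(matrix.shape, dtype=float)
    for k, total in enumerate(totals):
        if total > 0:
            cpm[:, k] = matrix[:, k] * 1e6 / total
        else:
            logger.warning("cluster %s has zero in-peak counts; CPM column left zero", clusters[k])
    return ClusterCounts(peaks=list(pc.peaks), clusters=list(clusters), matrix=matrix, cpm=cpm)


def cpm_filter(cc: ClusterCounts, threshold: float = 10.0, mode: str = "any") -> set[str]:
    """Peaks surviving the low-count filter (returns kept peak_ids).

    mode="any" (default): a peak is dropped only when its CPM is strictly
    below `threshold` in every cluster, i.e. kept when max CPM >= threshold.
    mode="sum": kept when the CPM summed over clusters >= threshold.
    A peak at exactly the threshold is kept (the removal rule is strict "<").
    """
    if mode == "any":
        keep = cc.cpm.max(axis=1) >= threshold
    elif mode == "sum":
        keep = cc.cpm.sum(axis=1) >= threshold
    else:
        raise ValueError(f"unknown cpm_filter mode {mode!r}")
    logger.info("cpm_filter(mode=%s): kept %d/%d peaks", mode, int(keep.sum()), len(cc.peaks))
    return {p.peak_id for p, k in zip(cc.peaks, keep) if k}


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _read_strand_window(genome: Mapping[str, str], peak: Peak, window: int, anchor: str) -> str:
    """The `window` nt immediately 3' (strand-aware) of the peak's anchor
    position, reverse-complemented for - peaks so it reads 5'->3' on the
    read strand. Truncated at chromosome ends."""
    seq = genome[peak.chrom]
    if anchor == "summit":
        pos3 = peak.summit
    elif anchor == "end":
        pos3 = peak.end - 1 if peak.strand == "+" else peak.start
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    if peak.strand == "+":
        lo, hi = pos3 + 1, min(len(seq), pos3 + 1 + window)
        if hi - lo < window:
            logger.warning("%s: window truncated at chromosome end", peak.peak_id)
        return str(seq[lo:hi]).upper()
    lo, hi = max(0, pos3 - window), pos3
    if hi - lo < window:
        logger.warning("%s: window truncated at chromosome start", peak.peak_id)
    return str(seq[lo:hi]).upper().translate(_COMPLEMENT)[::-1]


def _max_a_run(s: str) -> int:
    best = run = 0
    for ch in s:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    return best


def a_rich_filter(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    window: int = 20,
    max_a_frac: float = 0.70,
    max_a_run: int = 8,
    anchor: str = "summit",
) -> tuple[set[str], pd.DataFrame]:
    """Remove peaks whose downstream window is A-rich on the read strand
    (internal-priming artifacts).

    The window is the `window` nt immediately 3' of the peak summit (the
    estimated cleavage position; anchor="end" checks past the peak interval
    instead). A peak is removed when the A fraction reaches `max_a_frac` or
    the window contains a run of `max_a_run` or more consecutive A.
    Returns (kept peak_ids, removal report with the offending windows).
    """
    kept: set[str] = set()
    removed = []
    for p in peaks:
        win = _read_strand_window(genome, p, window, anchor)
        frac = win.count("A") / len(win) if win else 0.0
        run = _max_a_run(win)
        if win and (frac >= max_a_frac or run >= max_a_run):
            removed.append((p.peak_id, p.gene_id, win, round(frac, 4), run))
        else:
            kept.add(p.peak_id)
    report = pd.DataFrame(
        removed, columns=["peak_id", "gene_id", "window_seq", "a_fraction", "max_a_run"]
    )
    logger.info("a_rich_filter: removed %d/%d peaks", len(removed), len(peaks))
    return kept, report


def subset_peak_counts(pc: PeakCounts, keep_peak_ids: set[str]) -> PeakCounts:
    """PeakCounts restricted to the given peaks (order preserved)."""
    mask = [p.peak_id in keep_peak_ids for p in pc.peaks]
    rows = [i for i, m in enumerate(mask) if m]
    return PeakCounts(
        peaks=[pc.peaks[i] for i in rows],
        barcodes=pc.barcodes,
        matrix=pc.matrix[rows, :],
        cluster_of=pc.cluster_of,
        unassigned=pc.unassigned,
    )


def drop_single_peak_genes(peak_ids_or_peaks: Iterable[Peak]) -> set[str]:
    """Peak ids of genes retaining >= 2 peaks; single-peak genes carry no
    APA signal and are excluded from testing."""
    peaks = list(peak_ids_or_peaks)
    per_gene: dict[str, int] = {}
    for p in peaks:
        per_gene[p.gene_id] = per_gene.get(p.gene_id, 0) + 1
    return {p.peak_id for p in peaks if per_gene[p.gene_id] >= 2}


def write_mtx_triplet(pc: PeakCounts, outdir: str | Path, prefix: str = "peak_counts") -> dict[str, Path]:
    """MTX sparse matrix + peaks TSV + barcodes TSV triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / f"{prefix}.mtx",
        "peaks": outdir / f"{prefix}.peaks.tsv",
        "barcodes": outdir / f"{prefix}.barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), pc.matrix.tocoo())
    pd.DataFrame(
        [
            (p.peak_id, p.gene_id, p.chrom, p.start, p.end, p.strand, p.summit, p.order_index)
            for p in pc.peaks
        ],
        columns=["peak_id", "gene_id", "chrom", "start", "end", "strand", "summit", "order_index"],
    ).to_csv(paths["peaks"], sep="\t", index=False)
    pd.DataFrame(
        {"barcode": pc.barcodes, "cluster": [pc.cluster_of[b] for b in pc.barcodes]}
    ).to_csv(paths["barcodes"], sep="\t", index=False)
    return paths
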