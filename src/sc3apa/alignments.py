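"""Tagged-alignment ingestion, UMI deduplication and cell/gene quality control.

The unit record of the pipeline is a mapped read carrying a cell barcode and
a UMI (droplet scRNA-seq chemistry). Reads are assigned to genes by
strand-matched overlap with annotated 3'UTRs, collapsed to molecules on the
(barcode, gene, UMI) key, and the resulting UMI counts drive the standard
droplet QC: cells kept with 200-6000 detected genes and at most 10%
mitochondrial UMIs; genes kept when detected in at least 3 cells.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

from .peaks import UtrModel

logger = logging.getLogger(__name__)

__all__ = [
    "TaggedAlignment",
    "CellQcRecord",
    "UtrIndex",
    "read_tagged_alignments",
    "load_tagged_alignments",
    "deduplicate",
    "gene_cell_umi_counts",
    "qc_filter_cells",
    "filter_genes_min_cells",
]


@dataclass(frozen=True)
class TaggedAlignment:
    """One aligned read with barcode/UMI tags, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    barcode: str
    umi: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def terminus(self) -> int:
        """Strand-aware 3' terminus: last covered base on + , first on -."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class CellQcRecord:
    barcode: str
    n_genes: int
    pct_mito: float
    passed: bool


class UtrIndex:
    """Strand-aware interval lookup over non-overlapping 3'UTR models."""

    def __init__(self, utrs: Iterable[UtrModel]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[UtrModel]]] = {}
        grouped: dict[tuple[str, str], list[UtrModel]] = {}
        for u in utrs:
            grouped.setdefault((u.chrom, u.strand), []).append(u)
        for key, models in grouped.items():
            models.sort(key=lambda u: (u.utr_start, u.utr_end, u.gene_id))
            self._by_key[key] = ([u.utr_start for u in models], models)

    def assign(self, chrom: str, start: int, end: int, strand: str) -> UtrModel | None:
        """UTR overlapping [start, end) on `strand`, preferring the one that
        contains the read's 3' terminus; ties broken by gene_id."""
        entry = self._by_key.get((chrom, strand))
        if entry is None:
            return None
        starts, models = entry
        i = bisect_right(starts, end - 1)
        hits = []
        # UTRs are non-overlapping per strand, but a short read can straddle
        # two adjacent ones; scan the few candidates left of the insertion point.
        for j in range(max(0, i - 2), i):
            u = models[j]
            if u.utr_start < end and start < u.utr_end:
                hits.append(u)
        if not hits:
            return None
        terminus = end - 1 if strand == "+" else start
        containing = [u for u in hits if u.utr_start <= terminus < u.utr_end]
        pool = containing or hits
        pool.sort(key=lambda u: (-(min(end, u.utr_end) - max(start, u.utr_start)), u.gene_id))
        return pool[0]


def read_tagged_alignments(
    path: str,
    utrs: Iterable[UtrModel] | UtrIndex,
    cb_tag: str = "CB",
    ub_tag: str = "UB",
    stats: dict | None = None,
) -> Iterator[TaggedAlignment]:
    """Stream primary mapped reads from a SAM/BAM, assigning gene_id by
    strand-matched 3'UTR overlap.

    Reads missing either tag are counted in ``stats['missing_tags']`` and
    skipped. Reads overlapping no UTR are yielded with ``gene_id=None`` so
    callers can count them; downstream stages drop them.
    """
    index = utrs if isinstance(utrs, UtrIndex) else UtrIndex(utrs)
    counters = stats if stats is not None else {}
    counters.setdefault("records", 0)
    counters.setdefault("missing_tags", 0)
    counters.setdefault("unmapped_or_secondary", 0)
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            counters["records"] += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                counters["unmapped_or_secondary"] += 1
                continue
            if not rec.has_tag(cb_tag) or not rec.has_tag(ub_tag):
                counters["missing_tags"] += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            utr = index.assign(rec.reference_name, rec.reference_start, rec.reference_end, strand)
            yield TaggedAlignment(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand=strand,
                barcode=rec.get_tag(cb_tag),
                umi=rec.get_tag(ub_tag),
                gene_id=utr.gene_id if utr is not None else None,
            )


def load_tagged_alignments(
    path: str,
    utrs: Iterable[UtrModel] | UtrIndex,
    cb_tag: str = "CB",
    ub_tag: str = "UB",
) -> tuple[list[TaggedAlignment], dict]:
    """Materialise :func:`read_tagged_alignments`, returning (reads, stats)."""
    stats: dict = {}
    reads = list(read_tagged_alignments(path, utrs, cb_tag, ub_tag, stats=stats))
    stats["assigned"] = sum(1 for r in reads if r.gene_id is not None)
    stats["unassigned"] = len(reads) - stats["assigned"]
    return reads, stats


def _dedup_rank(read: TaggedAlignment) -> tuple:
    # Minimised: representative is the most-3' terminus (largest end for +,
    # smallest start for -), ties by smaller start then end.
    if read.strand == "+":
        return (-read.terminus, read.start, read.end)
    return (read.terminus, read.start, read.end)


def deduplicate(reads: Iterable[TaggedAlignment]) -> list[TaggedAlignment]:
    """Collapse PCR duplicates to one read per (barcode, gene_id, UMI) key.

    Exact-match UMI collapse: the retained representative is the read whose
    strand-aware 3' terminus is most 3'; ties resolved by smaller start
    coordinate, so the result is independent of input order. Idempotent.
    """
    best: dict[tuple[str, str, str], TaggedAlignment] = {}
    for r in reads:
        if r.gene_id is None:
            raise ValueError("deduplicate requires gene_id on every read")
        key = (r.barcode, r.gene_id, r.umi)
        cur = best.get(key)
        if cur is None or _dedup_rank(r) < _dedup_rank(cur):
            best[key] = r
    return list(best.values())


def gene_cell_umi_counts(reads: Iterable[TaggedAlignment]) -> pd.DataFrame:
    """Gene x cell molecule counts from deduplicated reads (one read = one UMI)."""
    tallies: dict[tuple[str, str], int] = {}
    for r in reads:
        if r.gene_id is None:
            continue
        key = (r.gene_id, r.barcode)
        tallies[key] = tallies.get(key, 0) + 1
    if not tallies:
        return pd.DataFrame(dtype=int)
    ser = pd.Series(tallies, dtype=int)
    ser.index = pd.MultiIndex.from_tuples(ser.index, names=["gene_id", "barcode"])
    return ser.unstack(fill_value=0).sort_index(axis=0).sort_index(axis=1)


def qc_filter_cells(
    counts: pd.DataFrame,
    mito_genes: Sequence[str] | None = None,
    min_genes: int = 200,
    max_genes: int = 6000,
    mito_max: float = 0.10,
    mito_prefix: str = "MT-",
) -> tuple[list[str], pd.DataFrame]:
    """Keep cells with min_genes <= detected genes <= max_genes and
    mitochondrial UMI fraction <= mito_max.

    `counts` is gene x cell UMI counts. Mitochondrial genes are either given
    explicitly or identified by name prefix (default "MT-"). A cell with zero
    total UMIs has pct_mito defined as 0 and fails on n_genes. Returns the
    kept barcodes and the per-cell QC table (barcode, n_genes, pct_mito, passed).
    """
    if counts.empty:
        return [], pd.DataFrame(columns=["barcode", "n_genes", "pct_mito", "passed"])
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if mito_genes is None:
        mito_idx = [g for g in counts.index if str(g).startswith(mito_prefix)]
    else:
        mito_idx = [g for g in counts.index if g in set(mito_genes)]
    n_genes = (counts > 0).sum(axis=0)
    total = counts.sum(axis=0)
    mito = counts.loc[mito_idx].sum(axis=0) if mito_idx else pd.Series(0, index=counts.columns)
    pct_mito = (mito / total.replace(0, 1)).where(total > 0, 0.0)
    passed = (n_genes >= min_genes) & (n_genes <= max_genes) & (pct_mito <= mito_max)
    table = pd.DataFrame(
        {
            "barcode": counts.columns,
            "n_genes": n_genes.to_numpy(),
            "pct_mito": pct_mito.to_numpy(),
            "passed": passed.to_numpy(),
        }
    )
    kept = [bc for bc, ok in zip(counts.columns, passed.to_numpy()) if ok]
    return kept, table


def filter_genes_min_cells(
    counts: pd.DataFrame,
    kept_cells: Sequence[str] | None = None,
    min_cells: int = 3,
) -> list[str]:
    """Genes detected (>=1 UMI) in at least `min_cells` of the kept cells."""
    if counts.empty:
        return []
    sub = counts if kept_cells is None else counts.loc[:, [c for c in counts.columns if c in set(kept_cells)]]
    n_cells = (sub > 0).sum(axis=1)
    return [g for g, n in n_cells.items() if n >= min_cells]


def subset_reads(
    reads: Iterable[TaggedAlignment],
    barcodes: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> list[TaggedAlignment]:
    """Reads restricted to the given barcodes/genes (None = no restriction)."""
    bc = set(barcodes) if barcodes is not None else None
    gn = set(genes) if genes is not None else None
    out = []
    for r in reads:
        if r.gene_id is None:
            continue
        if bc is not None and r.barcode not in bc:
            continue
        if gn is not None and r.gene_id not in gn:
            continue
        out.append(r)
    return out
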