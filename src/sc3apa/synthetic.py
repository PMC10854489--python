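"""Seedable generator of 3'-biased scRNA-seq data with known APA ground truth.

Emulates what a droplet 3'-end library looks like after alignment: each gene
is a single annotated 3'UTR on a synthetic chromosome; each molecule chooses
the proximal polyA site with a cluster-specific probability pi (the quantity
the downstream pipeline estimates) and leaves a read whose 3' terminus sits
at the chosen site minus a half-normal, strand-aware offset. PCR duplicates
share barcode, UMI and coordinates; internal-priming artifacts are planted
as genomic A-rich runs with a sharp read pileup immediately upstream, which
the A-rich peak filter must later remove.

Randomness is organised as one root seed with per-gene child streams (stable
spawn keys), so adding genes to a configuration does not perturb the reads
of existing genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignments import TaggedAlignment
from .peaks import UtrModel, write_utr_bed

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GENES_PER_CHROM = 50
_CHROM_FLANK = 500
ARTIFACT_OFFSET_SD = 5.0  # internal priming is templated at the A-run, so its pileup is sharp
ARTIFACT_RUN_LENGTH = 18

__all__ = [
    "SimConfig",
    "SimConfigError",
    "GeneModel",
    "SyntheticTruth",
    "SimulatedDataset",
    "simulate",
    "simulate_dataset",
    "simulate_gene_reads",
    "inject_pcr_duplicates",
    "inject_internal_priming",
    "write_truth",
    "read_truth",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    proximal_usage maps (gene_id, cluster) to the true proximal polyA-site
    usage probability pi; pairs not listed fall back to
    default_proximal_usage. With pas_per_gene > 2, pi is the proximal
    probability and the remaining mass is split evenly over the distal sites.
    """

    n_genes: int = 100
    n_clusters: int = 2
    cells_per_cluster: int = 100
    pas_per_gene: int = 2
    utr_length: int = 1000
    reads_per_gene_per_cell: float = 2.0
    proximal_usage: Mapping[tuple[str, str], float] | None = None
    default_proximal_usage: float = 0.5
    dup_rate: float = 0.3
    internal_priming_rate: float = 0.1
    artifact_read_fraction: float = 0.5
    fragment_offset_sd: float = 30.0
    read_length: int = 70
    pas_spacing: int = 300
    cluster_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_clusters", "cells_per_cluster", "utr_length",
                     "read_length", "pas_spacing"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise SimConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.pas_per_gene not in (1, 2, 3):
            raise SimConfigError(f"pas_per_gene must be 1, 2 or 3, got {self.pas_per_gene!r}")
        for name in ("dup_rate", "internal_priming_rate", "default_proximal_usage",
                     "artifact_read_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.dup_rate >= 1.0:
            raise SimConfigError("dup_rate must be < 1")
        if self.reads_per_gene_per_cell < 0:
            raise SimConfigError("reads_per_gene_per_cell must be non-negative")
        if self.fragment_offset_sd <= 0:
            raise SimConfigError("fragment_offset_sd must be positive")
        if self.utr_length < 300:
            raise SimConfigError("utr_length must be >= 300 nt")
        if self.utr_length < self._pas_margin() + (self.pas_per_gene - 1) * self.pas_spacing + 50:
            raise SimConfigError(
                "utr_length too short for pas_per_gene sites at pas_spacing separation"
            )
        if self.proximal_usage is not None:
            for key, pi in self.proximal_usage.items():
                if not (0.0 <= pi <= 1.0):
                    raise SimConfigError(f"proximal_usage[{key}] must be in [0, 1], got {pi!r}")
        if self.cluster_names is not None and len(self.cluster_names) != self.n_clusters:
            raise SimConfigError("cluster_names length must equal n_clusters")

    def _pas_margin(self) -> int:
        return max(150, int(4 * self.fragment_offset_sd))

    @property
    def clusters(self) -> tuple[str, ...]:
        if self.cluster_names is not None:
            return tuple(self.cluster_names)
        return tuple(f"cluster{i + 1}" for i in range(self.n_clusters))

    def gene_ids(self) -> list[str]:
        return [f"gene{i + 1:04d}" for i in range(self.n_genes)]

    def pi(self, gene_id: str, cluster: str) -> float:
        if self.proximal_usage is not None:
            key = (gene_id, cluster)
            if key in self.proximal_usage:
                return float(self.proximal_usage[key])
        return float(self.default_proximal_usage)


@dataclass(frozen=True)
class GeneModel:
    """One synthetic gene: its UTR and true polyA sites (proximal first)."""

    utr: UtrModel
    pas_positions: tuple[int, ...]
    artifact_anchors: tuple[int, ...] = ()

    @property
    def gene_id(self) -> str:
        return self.utr.gene_id


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation: gene models and per-(gene, cluster) usage."""

    genes: pd.DataFrame  # gene_id chrom strand utr_start utr_end pas_positions artifact_anchors
    usage: pd.DataFrame  # gene_id cluster pi n_true_reads n_artifact_reads


@dataclass
class SimulatedDataset:
    config: SimConfig
    chromosomes: dict[str, np.ndarray]  # name -> uint8 base codes 0..3
    genes: list[GeneModel]
    cells: pd.DataFrame  # barcode sample cell_type cluster
    reads: list[TaggedAlignment]  # post-duplication, as written to SAM
    truth: SyntheticTruth

    def chromosome_sequences(self) -> dict[str, str]:
        return {name: codes_to_seq(arr) for name, arr in self.chromosomes.items()}

    @property
    def utrs(self) -> list[UtrModel]:
        return [g.utr for g in self.genes]


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, gene_index)))


def _random_umi(rng: np.random.Generator, k: int = 10) -> str:
    return codes_to_seq(rng.integers(0, 4, size=k).astype(np.uint8))


def _layout_genes(config: SimConfig) -> tuple[dict[str, int], list[UtrModel], list[tuple[int, ...]]]:
    """Place non-overlapping single-gene UTRs, 50 genes per chromosome,
    alternating strands; returns chrom lengths, UTR models and PAS tuples."""
    margin = config._pas_margin()
    chrom_lengths: dict[str, int] = {}
    utrs: list[UtrModel] = []
    pas_list: list[tuple[int, ...]] = []
    for i, gene_id in enumerate(config.gene_ids()):
        chrom_idx, slot = divmod(i, _GENES_PER_CHROM)
        chrom = f"chrS{chrom_idx + 1}"
        start = _CHROM_FLANK + slot * (config.utr_length + _CHROM_FLANK)
        end = start + config.utr_length
        strand = "+" if i % 2 == 0 else "-"
        utr = UtrModel(gene_id=gene_id, chrom=chrom, strand=strand, utr_start=start, utr_end=end)
        if strand == "+":
            pas = tuple(start + margin + j * config.pas_spacing for j in range(config.pas_per_gene))
        else:
            pas = tuple(end - 1 - margin - j * config.pas_spacing for j in range(config.pas_per_gene))
        utrs.append(utr)
        pas_list.append(pas)
        chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), end + _CHROM_FLANK)
    return chrom_lengths, utrs, pas_list


def simulate_gene_reads(
    gene: GeneModel,
    cluster: str,
    n_reads: int,
    pi: float,
    offset_sd: float,
    rng: np.random.Generator,
    barcodes: Sequence[str],
    read_length: int = 70,
) -> list[TaggedAlignment]:
    """Reads of one gene in one cluster: each molecule picks the proximal PAS
    with probability pi (distal mass split evenly otherwise), and its 3'
    terminus is the chosen PAS shifted strand-aware upstream by a half-normal
    offset, truncated at the UTR boundary."""
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if not (0.0 <= pi <= 1.0):
        raise ValueError("pi must be in [0, 1]")
    if n_reads == 0:
        return []
    utr = gene.utr
    k = len(gene.pas_positions)
    proximal = rng.random(n_reads) < pi
    if k == 1:
        site_idx = np.zeros(n_reads, dtype=int)
    else:
        site_idx = np.where(proximal, 0, rng.integers(1, k, size=n_reads))
    pas = np.asarray(gene.pas_positions)[site_idx]
    offsets = np.rint(np.abs(rng.normal(0.0, offset_sd, size=n_reads))).astype(int)
    bc_idx = rng.integers(0, len(barcodes), size=n_reads)
    reads = []
    for j in range(n_reads):
        if utr.strand == "+":
            t = max(utr.utr_start, int(pas[j]) - offsets[j])
            start = max(utr.utr_start, t - read_length + 1)
            end = t + 1
        else:
            t = min(utr.utr_end - 1, int(pas[j]) + offsets[j])
            start = t
            end = min(utr.utr_end, t + read_length)
        reads.append(
            TaggedAlignment(
                chrom=utr.chrom, start=start, end=end, strand=utr.strand,
                barcode=barcodes[bc_idx[j]], umi=_random_umi(rng), gene_id=utr.gene_id,
            )
        )
    return reads


def inject_pcr_duplicates(
    reads: Sequence[TaggedAlignment], dup_rate: float, rng: np.random.Generator
) -> list[TaggedAlignment]:
    """Append PCR copies so that each emitted read is a duplicate with
    probability dup_rate; expected output size n/(1 - dup_rate). Copies share
    barcode, UMI, gene and coordinates with their template."""
    if not (0.0 <= dup_rate < 1.0):
        raise ValueError("dup_rate must be in [0, 1)")
    if dup_rate == 0.0:
        return list(reads)
    out = []
    for r in reads:
        out.append(r)
        # geometric(p=1-dup_rate) counts trials to first success; extra copies
        extras = int(rng.geometric(1.0 - dup_rate)) - 1
        out.extend([r] * extras)
    return out


def inject_internal_priming(
    chrom_codes: np.ndarray,
    gene: GeneModel,
    rate: float,
    rng: np.random.Generator,
    run_length: int = ARTIFACT_RUN_LENGTH,
    min_distance: int = 150,
) -> GeneModel:
    """With probability `rate`, write an A-rich run (A on the read strand)
    into the UTR interior at least `min_distance` from every true PAS, and
    record the pileup anchor immediately strand-aware upstream of the run.

    Mutates chrom_codes in place; returns the gene with artifact anchors set.
    A UTR with no admissible placement is skipped with a warning.
    """
    if rng.random() >= rate:
        return gene
    utr = gene.utr
    margin = 60  # keep the run and its pileup clear of UTR boundaries
    lo = utr.utr_start + margin
    hi = utr.utr_end - margin - run_length
    if hi <= lo:
        logger.warning("%s: UTR too short to place internal-priming artifact", utr.gene_id)
        return gene
    candidates = np.arange(lo, hi)
    anchors = candidates - 1 if utr.strand == "+" else candidates + run_length
    ok = np.ones(len(candidates), dtype=bool)
    for pas in gene.pas_positions:
        ok &= np.abs(anchors - pas) >= min_distance
    if not ok.any():
        logger.warning("%s: no artifact placement %d nt clear of PAS", utr.gene_id, min_distance)
        return gene
    q = int(rng.choice(candidates[ok]))
    base = 0 if utr.strand == "+" else 3  # A on + reference, T on - (A on the read strand)
    chrom_codes[q : q + run_length] = base
    anchor = q - 1 if utr.strand == "+" else q + run_length
    return GeneModel(utr=utr, pas_positions=gene.pas_positions,
                     artifact_anchors=gene.artifact_anchors + (anchor,))


def _make_cells(config: SimConfig) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    n = config.n_clusters * config.cells_per_cluster
    seen: set[str] = set()
    barcodes: list[str] = []
    while len(barcodes) < n:
        bc = codes_to_seq(rng.integers(0, 4, size=16).astype(np.uint8))
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    rows = []
    for ci, cluster in enumerate(config.clusters):
        for j in range(config.cells_per_cluster):
            bc = barcodes[ci * config.cells_per_cluster + j]
            rows.append((bc, f"sample_{cluster}", cluster, cluster))
    return pd.DataFrame(rows, columns=["barcode", "sample", "cell_type", "cluster"])


def simulate(config: SimConfig) -> SimulatedDataset:
    """Generate a full in-memory dataset: genome, gene models, cells, reads
    (with PCR duplicates) and the ground-truth tables."""
    chrom_lengths, utrs, pas_list = _layout_genes(config)
    chromosomes = {
        name: np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(2, ci))
        ).integers(0, 4, size=length).astype(np.uint8)
        for ci, (name, length) in enumerate(chrom_lengths.items())
    }
    cells = _make_cells(config)
    cluster_barcodes = {
        cl: cells.loc[cells["cluster"] == cl, "barcode"].tolist() for cl in config.clusters
    }

    genes: list[GeneModel] = []
    all_reads: list[TaggedAlignment] = []
    usage_rows = []
    for gi, (utr, pas) in enumerate(zip(utrs, pas_list)):
        rng = _gene_rng(config.seed, gi)
        gene = GeneModel(utr=utr, pas_positions=pas)
        gene = inject_internal_priming(
            chromosomes[utr.chrom], gene, config.internal_priming_rate, rng
        )
        gene_reads: list[TaggedAlignment] = []
        for cluster in config.clusters:
            bcs = cluster_barcodes[cluster]
            pi = config.pi(utr.gene_id, cluster)
            n_true = int(rng.poisson(config.reads_per_gene_per_cell * len(bcs)))
            gene_reads.extend(
                simulate_gene_reads(gene, cluster, n_true, pi, config.fragment_offset_sd,
                                    rng, bcs, config.read_length)
            )
            n_art = 0
            for anchor in gene.artifact_anchors:
                n_art = max(10, round(config.artifact_read_fraction * n_true))
                fake = GeneModel(utr=utr, pas_positions=(anchor,))
                gene_reads.extend(
                    simulate_gene_reads(fake, cluster, n_art, 1.0, ARTIFACT_OFFSET_SD,
                                        rng, bcs, config.read_length)
                )
            usage_rows.append((utr.gene_id, cluster, pi, n_true, n_art))
        gene_reads = inject_pcr_duplicates(gene_reads, config.dup_rate, rng)
        genes.append(gene)
        all_reads.extend(gene_reads)

    genes_df = pd.DataFrame(
        [
            (
                g.gene_id, g.utr.chrom, g.utr.strand, g.utr.utr_start, g.utr.utr_end,
                ",".join(map(str, g.pas_positions)),
                ",".join(map(str, g.artifact_anchors)),
            )
            for g in genes
        ],
        columns=["gene_id", "chrom", "strand", "utr_start", "utr_end",
                 "pas_positions", "artifact_anchors"],
    )
    usage_df = pd.DataFrame(
        usage_rows, columns=["gene_id", "cluster", "pi", "n_true_reads", "n_artifact_reads"]
    )
    return SimulatedDataset(
        config=config, chromosomes=chromosomes, genes=genes, cells=cells,
        reads=all_reads, truth=SyntheticTruth(genes=genes_df, usage=usage_df),
    )


def write_sam(reads: Sequence[TaggedAlignment], chrom_lengths: Mapping[str, int], path: str) -> None:
    """Coordinate-sorted SAM with CB/UB tags; deterministic byte-for-byte."""
    names = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(chrom_lengths[n])} for n in names],
    }
    order = {n: i for i, n in enumerate(names)}
    indexed = sorted(
        enumerate(reads),
        key=lambda t: (order[t[1].chrom], t[1].start, t[1].end, t[1].barcode, t[1].umi, t[0]),
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for serial, (_, r) in enumerate(indexed):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{serial:08d}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = order[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigartuples = [(0, r.end - r.start)]
            a.set_tags([("CB", r.barcode, "Z"), ("UB", r.umi, "Z")])
            out.write(a)


def write_truth(truth: SyntheticTruth, genes_path: str, usage_path: str) -> None:
    truth.genes.to_csv(genes_path, sep="\t", index=False)
    truth.usage.to_csv(usage_path, sep="\t", index=False)


def read_truth(genes_path: str, usage_path: str) -> SyntheticTruth:
    genes = pd.read_csv(genes_path, sep="\t", dtype={"pas_positions": str, "artifact_anchors": str},
                        keep_default_na=False)
    usage = pd.read_csv(usage_path, sep="\t")
    return SyntheticTruth(genes=genes, usage=usage)


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write the dataset bundle; returns the output paths.

    Files: genome.fa, utrs.bed (BED6), reads.sam (tags CB/UB), cells.tsv,
    truth_genes.tsv, truth_usage.tsv. Byte-identical across runs with the
    same config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate(config)
    paths = {
        "genome": outdir / "genome.fa",
        "utr_bed": outdir / "utrs.bed",
        "sam": outdir / "reads.sam",
        "cells": outdir / "cells.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_usage": outdir / "truth_usage.tsv",
    }
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in ds.chromosome_sequences().items()
    ]
    SeqIO.write(records, str(paths["genome"]), "fasta")
    write_utr_bed(ds.utrs, str(paths["utr_bed"]))
    write_sam(ds.reads, {n: len(c) for n, c in ds.chromosomes.items()}, str(paths["sam"]))
    ds.cells.to_csv(paths["cells"], sep="\t", index=False)
    write_truth(ds.truth, str(paths["truth_genes"]), str(paths["truth_usage"]))
    return paths
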