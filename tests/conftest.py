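import numpy as np
import pytest
import scipy.sparse as sp

from sc3apa.peaks import Peak, UtrModel
from sc3apa.quantify import PeakCounts
from sc3apa.synthetic import SimConfig, simulate


@pytest.fixture
def plus_utr():
    return UtrModel(gene_id="gA", chrom="chr1", strand="+", utr_start=1000, utr_end=2000)


@pytest.fixture
def minus_utr():
    return UtrModel(gene_id="gB", chrom="chr1", strand="-", utr_start=3000, utr_end=4000)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-cluster dataset with a usage shift and planted artifacts."""
    gene_ids = [f"gene{i + 1:04d}" for i in range(12)]
    usage = {}
    for g in gene_ids[:6]:
        usage[(g, "normal")] = 0.3
        usage[(g, "tumor")] = 0.7
    cfg = SimConfig(
        n_genes=12,
        n_clusters=2,
        cells_per_cluster=40,
        cluster_names=("normal", "tumor"),
        reads_per_gene_per_cell=6.0,
        proximal_usage=usage,
        default_proximal_usage=0.5,
        dup_rate=0.4,
        internal_priming_rate=0.25,
        seed=11,
    )
    return simulate(cfg)


def make_peak_counts(matrix, gene_of_peak, barcodes, cluster_of):
    """Assemble a PeakCounts around an explicit dense matrix.

    gene_of_peak lists (gene_id, order_index) per row; peak coordinates are
    synthesised on a dummy chromosome, spaced apart.
    """
    peaks = []
    for i, (gene, order) in enumerate(gene_of_peak):
        start = 1000 * (i + 1)
        peaks.append(
            Peak(
                peak_id=f"{gene}|{order}",
                gene_id=gene,
                chrom="chrT",
                strand="+",
                start=start,
                end=start + 200,
                summit=start + 100,
                order_index=order,
            )
        )
    m = sp.csr_matrix(np.asarray(matrix, dtype=np.int64))
    return PeakCounts(
        peaks=peaks, barcodes=list(barcodes), matrix=m, cluster_of=dict(cluster_of)
    )
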