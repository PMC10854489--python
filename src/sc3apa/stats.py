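"""APA statistics: proximal usage, per-cell mean proximal polyA-site usage
index (PUI), per-gene differential APA tests and distribution comparisons.

Proximal usage of a gene in a unit (cell or cluster) is the fraction of the
gene's in-peak molecules assigned to its most proximal peak; with more than
two peaks the distal peaks are pooled, so "shortening" is monotone in
proximal mass. The per-cell mean proximal PUI averages (optionally
z-standardised) usage over the cell's informative genes: a higher value
means more cleavage at proximal sites, i.e. globally shorter 3'UTRs in that
cell. Differential APA between two cell groups is a Pearson chi-square on
the gene's peak x group count table with BH correction across genes;
shifts in the PUI distribution between groups are assessed with the
tie-corrected, continuity-corrected normal approximation of the Wilcoxon
rank-sum test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .quantify import ClusterCounts, PeakCounts

logger = logging.getLogger(__name__)

__all__ = [
    "ApaGeneTest",
    "WilcoxonResult",
    "proximal_usage",
    "gene_usage_per_cell",
    "mean_proximal_pui",
    "diff_apa_test",
    "diff_apa_all",
    "benjamini_hochberg",
    "wilcoxon_rank_sum",
    "classify_events",
]


@dataclass(frozen=True)
class ApaGeneTest:
    """Per-gene differential APA result.

    delta_proximal is usage(group B) - usage(group A) at group level, so with
    B = tumor-like group, call="shortened" means higher proximal usage in B.
    """

    gene_id: str
    statistic: float
    df: int
    p: float
    q: float | None = None
    delta_proximal: float = math.nan
    call: str = "ns"


@dataclass(frozen=True)
class WilcoxonResult:
    u_statistic: float
    z: float
    p_two_sided: float


def proximal_usage(counts: np.ndarray) -> float:
    """Proximal-usage fraction from a gene's peak counts ordered by
    order_index (proximal first): counts[0] / counts.sum().

    Returns NaN when the unit has no counts for the gene; requires >= 2
    peaks (a single-peak gene has no APA signal).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("proximal usage needs >= 2 ordered peak counts")
    total = counts.sum()
    if total == 0:
        return math.nan
    return float(counts[0] / total)


def _gene_rows(pc: PeakCounts) -> dict[str, list[int]]:
    rows: dict[str, list[int]] = {}
    for i, p in enumerate(pc.peaks):
        rows.setdefault(p.gene_id, []).append(i)
    for gene, idx in rows.items():
        idx.sort(key=lambda i: pc.peaks[i].order_index or 0)
    return rows


def gene_usage_per_cell(pc: PeakCounts, gene_id: str) -> np.ndarray:
    """Per-cell proximal usage of one gene; NaN where the cell has no counts."""
    rows = _gene_rows(pc).get(gene_id)
    if rows is None or len(rows) < 2:
        raise ValueError(f"{gene_id}: gene not present with >= 2 peaks")
    sub = np.asarray(pc.matrix[rows, :].todense(), dtype=float)
    totals = sub.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = np.where(totals > 0, sub[0] / np.where(totals > 0, totals, 1), np.nan)
    return usage


def mean_proximal_pui(
    pc: PeakCounts,
    mode: str = "standardized",
    min_genes_per_cell: int = 10,
) -> pd.DataFrame:
    """Per-cell mean proximal PUI over the cell's informative multi-peak genes.

    In "raw" mode the per-gene, per-cell proximal usage (in [0, 1]) is
    averaged directly; in "standardized" mode each gene's usage is first
    z-scored across the cells where it is defined (genes with zero variance
    contribute to no cell), which weights genes equally regardless of their
    baseline usage. Cells with fewer than `min_genes_per_cell` defined genes
    are omitted. Returns a DataFrame (barcode, mean_proximal_pui,
    n_genes_used).
    """
    if mode not in ("raw", "standardized"):
        raise ValueError(f"unknown PUI mode {mode!r}")
    genes = [g for g, rows in _gene_rows(pc).items() if len(rows) >= 2]
    n_cells = len(pc.barcodes)
    total = np.zeros(n_cells)
    used = np.zeros(n_cells, dtype=int)
    for gene in genes:
        usage = gene_usage_per_cell(pc, gene)
        defined = ~np.isnan(usage)
        if mode == "standardized":
            vals = usage[defined]
            if len(vals) < 2:
                continue
            sd = vals.std(ddof=1)
            if sd == 0:
                continue  # uninformative gene: identical usage wherever defined
            usage = (usage - vals.mean()) / sd
        total[defined] += usage[defined]
        used[defined] += 1
    if not genes:
        logger.warning("mean_proximal_pui: no multi-peak genes available")
    keep = used >= min_genes_per_cell
    with np.errstate(invalid="ignore"):
        mean = np.where(used > 0, total / np.where(used > 0, used, 1), np.nan)
    return pd.DataFrame(
        {
            "barcode": [bc for bc, k in zip(pc.barcodes, keep) if k],
            "mean_proximal_pui": mean[keep],
            "n_genes_used": used[keep],
        }
    )


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Raises ValueError when any expected count is zero (a zero row or column
    sum), matching the pipeline's skip-and-report behaviour.
    """
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero expected count: degenerate margin")
    stat, p, df, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def diff_apa_test(
    cc: ClusterCounts,
    gene_id: str,
    group_a: list[str],
    group_b: list[str],
) -> ApaGeneTest | None:
    """Chi-square test of the gene's peak x group count table (counts summed
    within each group); delta_proximal = usage(B) - usage(A). Returns None
    (gene untested) when a margin of the table is zero."""
    table_a = cc.gene_table(gene_id, group_a).sum(axis=1)
    table_b = cc.gene_table(gene_id, group_b).sum(axis=1)
    if len(table_a) < 2:
        raise ValueError(f"{gene_id}: differential APA needs >= 2 retained peaks")
    table = np.column_stack([table_a, table_b])
    try:
        stat, df, p = chi_square_independence(table)
    except ValueError:
        return None
    delta = proximal_usage(table_b) - proximal_usage(table_a)
    return ApaGeneTest(gene_id=gene_id, statistic=stat, df=df, p=p, delta_proximal=delta)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_apa_all(
    cc: ClusterCounts,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every gene with >= 2 retained peaks; BH across tested genes and
    classify calls (shortened: q < alpha and delta_proximal > 0; lengthened:
    q < alpha and delta < 0). Untestable genes appear with call="untested"."""
    genes: dict[str, int] = {}
    for p in cc.peaks:
        genes[p.gene_id] = genes.get(p.gene_id, 0) + 1
    rows = []
    tested: list[ApaGeneTest] = []
    for gene_id, n_peaks in genes.items():
        if n_peaks < 2:
            continue
        res = diff_apa_test(cc, gene_id, group_a, group_b)
        if res is None:
            rows.append((gene_id, math.nan, 0, math.nan, math.nan, math.nan, "untested"))
        else:
            tested.append(res)
    qs = benjamini_hochberg([t.p for t in tested])
    for t, q in zip(tested, qs):
        if q < alpha and t.delta_proximal > 0:
            call = "shortened"
        elif q < alpha and t.delta_proximal < 0:
            call = "lengthened"
        else:
            call = "ns"
        rows.append((t.gene_id, t.statistic, t.df, t.p, float(q), t.delta_proximal, call))
    out = pd.DataFrame(
        rows, columns=["gene_id", "statistic", "df", "p", "q", "delta_proximal", "call"]
    )
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> WilcoxonResult:
    """Two-sample Wilcoxon (Mann-Whitney) rank-sum test, normal
    approximation with midranks, tie-corrected variance and (by default) a
    0.5 continuity correction; two-sided p from the normal tail.

    Degenerate case: when the pooled sample is constant (zero variance) the
    result is U = n1*n2/2, z = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # U statistic of sample x
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    if n > 1:
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        var = 0.0
    if var <= 0:
        return WilcoxonResult(u_statistic=float(u), z=0.0, p_two_sided=1.0)
    num = abs(u - mu) - (0.5 if continuity else 0.0)
    z = max(0.0, num) / math.sqrt(var)
    p = min(1.0, 2.0 * scipy.stats.norm.sf(z))
    return WilcoxonResult(u_statistic=float(u), z=float(z), p_two_sided=float(p))


def classify_events(tests: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Summarise shortened/lengthened calls and their ratio.

    Recomputes calls from q and delta_proximal at the given alpha so the
    summary threshold can differ from the one used in diff_apa_all. ratio is
    NaN when no lengthened genes exist.
    """
    ok = tests.dropna(subset=["q"])
    short = int(((ok["q"] < alpha) & (ok["delta_proximal"] > 0)).sum())
    long_ = int(((ok["q"] < alpha) & (ok["delta_proximal"] < 0)).sum())
    ratio = short / long_ if long_ > 0 else math.nan
    return {"n_shortened": short, "n_lengthened": long_, "ratio": ratio}
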