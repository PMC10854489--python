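"""Canonical synthetic study scenarios used by the analysis scripts and the
reproducibility script.

Each scenario fixes the generator's study conditions once (sample sizes,
usage probabilities, duplication and artifact rates) so that analyses,
validation runs and documentation all refer to the same datasets. Seeds are
taken as arguments so a whole run can be re-randomised coherently.
"""

from __future__ import annotations

from .synthetic import SimConfig

__all__ = [
    "tumor_vs_normal_config",
    "tumor_vs_normal_run_config",
    "summit_recovery_config",
    "artifact_filter_config",
    "usage_recovery_config",
    "operating_characteristics_config",
    "pui_direction_config",
]


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i + 1:04d}" for i in range(n)]


def tumor_vs_normal_config(seed: int) -> SimConfig:
    """Two-condition cohort emulating a tumor-vs-normal comparison.

    300 genes across a "normal" and a "tumor" cluster of 50 cells each:
    50 genes shift toward proximal usage in tumor (pi 0.5 -> 0.8, 3'UTR
    shortening), 10 shift away (0.8 -> 0.5, lengthening), the rest are null
    at pi 0.5 — a 5:1 imbalance of planted shortening over lengthening.
    Depth ~8 reads/gene/cell keeps both polyA sites of every gene above the
    peak caller's height floor; 30% PCR duplication and a 10% internal-
    priming rate exercise dedup and the A-rich filter on the way.
    """
    genes = _gene_ids(300)
    usage: dict[tuple[str, str], float] = {}
    for g in genes[:50]:
        usage[(g, "normal")] = 0.5
        usage[(g, "tumor")] = 0.8
    for g in genes[50:60]:
        usage[(g, "normal")] = 0.8
        usage[(g, "tumor")] = 0.5
    return SimConfig(
        n_genes=300,
        n_clusters=2,
        cells_per_cluster=50,
        cluster_names=("normal", "tumor"),
        reads_per_gene_per_cell=8.0,
        proximal_usage=usage,
        default_proximal_usage=0.5,
        dup_rate=0.3,
        internal_priming_rate=0.1,
        seed=seed,
    )


def tumor_vs_normal_run_config(outdir, seed: int) -> dict:
    """Full pipeline configuration over :func:`tumor_vs_normal_config`.

    Cell QC thresholds are rescaled to the simulated panel (300 genes): the
    defaults target genome-wide droplet data and would reject every
    synthetic cell.
    """
    cfg = tumor_vs_normal_config(seed)
    return {
        "outdir": str(outdir),
        "seed": seed,
        "simulate": {
            **{k: v for k, v in vars(cfg).items() if k not in ("proximal_usage", "cluster_names")},
            "proximal_usage": {f"{g}/{c}": v for (g, c), v in cfg.proximal_usage.items()},
            "cluster_names": list(cfg.cluster_names),
        },
        "groups": {"a": ["normal"], "b": ["tumor"]},
        "params": {"qc": {"min_genes": 50}, "pui": {"min_genes_per_cell": 10}},
    }


def summit_recovery_config(seed: int) -> SimConfig:
    """100 two-site genes, sites 300 nt apart, ~250 reads per site."""
    return SimConfig(
        n_genes=100, n_clusters=1, cells_per_cluster=50,
        reads_per_gene_per_cell=10.0, dup_rate=0.0,
        internal_priming_rate=0.0, pas_spacing=300, seed=seed,
    )


def artifact_filter_config(seed: int) -> SimConfig:
    """60 genes, every one carrying a planted internal-priming artifact."""
    return SimConfig(
        n_genes=60, n_clusters=1, cells_per_cluster=50,
        reads_per_gene_per_cell=6.0, dup_rate=0.0,
        internal_priming_rate=1.0, seed=seed,
    )


def usage_recovery_config(seed: int) -> SimConfig:
    """8 genes x 2 clusters spanning pi 0.2-0.8 at ~10^4 reads/gene/cluster."""
    pis = [0.2, 0.35, 0.5, 0.65, 0.8, 0.3, 0.6, 0.75]
    usage = {}
    for g, pi in zip(_gene_ids(8), pis):
        usage[(g, "c1")] = pi
        usage[(g, "c2")] = 1.0 - pi
    return SimConfig(
        n_genes=8, n_clusters=2, cells_per_cluster=100,
        cluster_names=("c1", "c2"), reads_per_gene_per_cell=100.0,
        proximal_usage=usage, dup_rate=0.0, internal_priming_rate=0.0,
        seed=seed,
    )


def operating_characteristics_config(seed: int) -> SimConfig:
    """500 null genes plus 50 genes with a +0.3 proximal-usage shift at
    ~400 in-peak counts per group per gene."""
    genes = _gene_ids(550)
    usage = {}
    for g in genes[:500]:
        usage[(g, "a")] = usage[(g, "b")] = 0.5
    for g in genes[500:]:
        usage[(g, "a")] = 0.5
        usage[(g, "b")] = 0.8
    return SimConfig(
        n_genes=550, n_clusters=2, cells_per_cluster=50,
        cluster_names=("a", "b"), reads_per_gene_per_cell=8.0,
        proximal_usage=usage, dup_rate=0.0, internal_priming_rate=0.0,
        seed=seed,
    )


def pui_direction_config(seed: int) -> SimConfig:
    """100 genes, clusters of 200 cells at pi 0.8 ("hi") vs 0.4 ("lo")."""
    usage = {}
    for g in _gene_ids(100):
        usage[(g, "hi")] = 0.8
        usage[(g, "lo")] = 0.4
    return SimConfig(
        n_genes=100, n_clusters=2, cells_per_cluster=200,
        cluster_names=("hi", "lo"), reads_per_gene_per_cell=2.0,
        proximal_usage=usage, dup_rate=0.0, internal_priming_rate=0.0,
        seed=seed,
    )
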