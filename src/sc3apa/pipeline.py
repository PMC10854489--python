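"""End-to-end orchestration: config validation, stage sequencing, manifest.

The stage order follows the analysis the pipeline implements: deduplicate
UMIs, apply cell/gene QC, call 3'UTR peaks on the pooled deduplicated reads,
count reads in peaks per cell, filter peaks (low-count CPM, A-rich), then
compute per-cell PUI and per-gene differential APA between two cell groups.
Every run writes a machine-readable manifest (config echo, package version,
per-stage record counts, output checksums); the pipeline is deterministic
given the seed, so rerunning a config reproduces identical checksums.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import pyfaidx
import yaml

from . import __version__
from .alignments import (
    deduplicate,
    filter_genes_min_cells,
    gene_cell_umi_counts,
    load_tagged_alignments,
    qc_filter_cells,
    subset_reads,
)
from .peaks import (
    call_peaks,
    compute_utr_coverage,
    read_utr_bed,
    write_bedgraph,
    write_peaks_bed,
)
from .quantify import (
    a_rich_filter,
    aggregate_by_cluster,
    count_reads_in_peaks,
    cpm_filter,
    drop_single_peak_genes,
    subset_peak_counts,
    write_mtx_triplet,
)
from .stats import classify_events, diff_apa_all, mean_proximal_pui, wilcoxon_rank_sum
from .synthetic import SimConfig, SimConfigError, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "load", "dedup", "qc", "peaks", "count", "filter", "pui", "diffapa")


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending key."""


_SIM_KEYS = {
    "n_genes", "n_clusters", "cells_per_cluster", "pas_per_gene", "utr_length",
    "reads_per_gene_per_cell", "proximal_usage", "default_proximal_usage",
    "dup_rate", "internal_priming_rate", "artifact_read_fraction",
    "fragment_offset_sd", "read_length", "pas_spacing", "cluster_names", "seed",
}

_SCHEMA: dict[str, dict[str, Any]] = {
    "tags": {"cb": "CB", "ub": "UB"},
    "qc": {"min_genes": 200, "max_genes": 6000, "mito_max": 0.10,
           "min_cells": 3, "mito_prefix": "MT-"},
    "peaks": {"min_height": 5, "half_width": 100, "min_separation": 150,
              "template_sd": 30.0},
    "filters": {"cpm_threshold": 10.0, "cpm_mode": "any", "a_window": 20,
                "a_max_frac": 0.70, "a_max_run": 8, "a_anchor": "summit"},
    "pui": {"mode": "standardized", "min_genes_per_cell": 10},
    "test": {"alpha": 0.05},
}

_TOP_KEYS = {"simulate", "inputs", "outdir", "seed", "groups", "params"}
_INPUT_KEYS = {"sam", "genome", "utr_bed", "cells"}


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    sim: SimConfig | None = None
    inputs: dict[str, Path] | None = None
    groups: tuple[list[str], list[str]] | None = None
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def param(self, section: str, key: str) -> Any:
        return self.params[section][key]


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    counts: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "counts": self.counts,
            "checksums": self.checksums,
            "completed_stages": self.completed_stages,
            "failed_stage": self.failed_stage,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _reject_unknown(given: Mapping, allowed: set[str], where: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(str(key), [str(a) for a in allowed], n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {where}{suggestion}")


def validate_config(source: str | Path | Mapping) -> RunConfig:
    """Parse and validate a run configuration (YAML path or mapping).

    Exactly one of `simulate` / `inputs` must be present; unknown keys are
    rejected with a closest-match suggestion; referenced input files must
    exist. Stage parameters default per module.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    if "outdir" not in raw:
        raise ConfigError("missing required key 'outdir'")
    has_sim = "simulate" in raw and raw["simulate"] is not None
    has_inputs = "inputs" in raw and raw["inputs"] is not None
    if has_sim == has_inputs:
        raise ConfigError("exactly one of 'simulate' and 'inputs' must be given")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"'seed' must be an integer, got {seed!r}")

    sim = None
    inputs = None
    if has_sim:
        block = dict(raw["simulate"])
        _reject_unknown(block, _SIM_KEYS, "simulate")
        if "proximal_usage" in block and block["proximal_usage"] is not None:
            block["proximal_usage"] = {
                (g, c): float(v)
                for (g, c), v in (
                    ((k.split("/", 1)[0], k.split("/", 1)[1]), v)
                    for k, v in block["proximal_usage"].items()
                )
            } if isinstance(raw["simulate"]["proximal_usage"], Mapping) else block["proximal_usage"]
        if "cluster_names" in block and block["cluster_names"] is not None:
            block["cluster_names"] = tuple(block["cluster_names"])
        block.setdefault("seed", seed)
        try:
            sim = SimConfig(**block)
        except SimConfigError as exc:
            raise ConfigError(f"simulate: {exc}") from exc
    else:
        block = dict(raw["inputs"])
        _reject_unknown(block, _INPUT_KEYS, "inputs")
        missing_keys = _INPUT_KEYS - set(block)
        if missing_keys:
            raise ConfigError(f"inputs missing required key(s): {sorted(missing_keys)}")
        inputs = {k: Path(v) for k, v in block.items()}
        for k, path in inputs.items():
            if not path.exists():
                raise ConfigError(f"inputs.{k}: file not found: {path}")

    groups = None
    if raw.get("groups") is not None:
        gblock = dict(raw["groups"])
        _reject_unknown(gblock, {"a", "b"}, "groups")
        a = list(gblock.get("a") or [])
        b = list(gblock.get("b") or [])
        groups = (a, b)

    params = {section: dict(defaults) for section, defaults in _SCHEMA.items()}
    for section, overrides in (raw.get("params") or {}).items():
        if section not in _SCHEMA:
            hint = difflib.get_close_matches(section, list(_SCHEMA), n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown key {section!r} in params{suggestion}")
        _reject_unknown(overrides or {}, set(_SCHEMA[section]), f"params.{section}")
        params[section].update(overrides or {})
    return RunConfig(outdir=Path(raw["outdir"]), seed=seed, sim=sim, inputs=inputs,
                     groups=groups, params=params)


@dataclass
class PipelineResult:
    manifest: RunManifest
    peaks: list = field(default_factory=list)
    peak_counts: Any = None
    cluster_counts: Any = None
    pui: pd.DataFrame | None = None
    tests: pd.DataFrame | None = None
    summary: dict | None = None
    group_comparison: pd.DataFrame | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_echo(cfg: RunConfig) -> dict:
    echo: dict[str, Any] = {
        "outdir": str(cfg.outdir),
        "seed": cfg.seed,
        "groups": list(cfg.groups) if cfg.groups else None,
        "params": cfg.params,
    }
    if cfg.sim is not None:
        echo["simulate"] = {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg.sim).items()
        }
        if echo["simulate"].get("proximal_usage"):
            echo["simulate"]["proximal_usage"] = {
                f"{g}/{c}": v for (g, c), v in cfg.sim.proximal_usage.items()
            }
    if cfg.inputs is not None:
        echo["inputs"] = {k: str(v) for k, v in cfg.inputs.items()}
    return echo


def run_pipeline(cfg: RunConfig, through_stage: str = "diffapa") -> PipelineResult:
    """Run the pipeline up to (and including) `through_stage`.

    Writes all stage outputs and a manifest under cfg.outdir; the manifest is
    written even when a stage fails, recording the stages completed so far.
    """
    if through_stage not in STAGES:
        raise ConfigError(f"unknown stage {through_stage!r}")
    stop_after = STAGES.index(through_stage)
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_echo(cfg))
    result = PipelineResult(manifest=manifest)
    manifest_path = outdir / "manifest.json"

    def done(stage: str) -> bool:
        manifest.completed_stages.append(stage)
        return STAGES.index(stage) >= stop_after

    try:
        # --- inputs -----------------------------------------------------
        if cfg.sim is not None:
            sim_cfg = cfg.sim if cfg.sim.seed == cfg.seed else SimConfig(
                **{**vars(cfg.sim), "seed": cfg.seed}
            )
            paths = simulate_dataset(sim_cfg, outdir / "sim")
            result.paths.update(paths)
            if done("simulate"):
                return _finish(result, manifest, manifest_path)
        else:
            paths = dict(cfg.inputs)
            result.paths.update(paths)

        utrs = read_utr_bed(str(paths["utr_bed"]))
        cells_df = pd.read_csv(paths["cells"], sep="\t", dtype=str)
        cluster_of = dict(zip(cells_df["barcode"], cells_df["cluster"]))
        reads, load_stats = load_tagged_alignments(
            str(paths["sam"]), utrs, cfg.param("tags", "cb"), cfg.param("tags", "ub")
        )
        manifest.counts["sam_records"] = load_stats["records"]
        manifest.counts["reads_missing_tags"] = load_stats["missing_tags"]
        manifest.counts["reads_gene_assigned"] = load_stats["assigned"]
        if done("load"):
            return _finish(result, manifest, manifest_path)

        # --- dedup ------------------------------------------------------
        assigned = [r for r in reads if r.gene_id is not None]
        deduped = deduplicate(assigned)
        manifest.counts["reads_deduplicated"] = len(deduped)
        if done("dedup"):
            return _finish(result, manifest, manifest_path)

        # --- cell / gene QC --------------------------------------------
        umi_counts = gene_cell_umi_counts(deduped)
        kept_cells, qc_table = qc_filter_cells(
            umi_counts,
            min_genes=cfg.param("qc", "min_genes"),
            max_genes=cfg.param("qc", "max_genes"),
            mito_max=cfg.param("qc", "mito_max"),
            mito_prefix=cfg.param("qc", "mito_prefix"),
        )
        kept_genes = filter_genes_min_cells(umi_counts, kept_cells, cfg.param("qc", "min_cells"))
        qc_table.to_csv(outdir / "cell_qc.tsv", sep="\t", index=False)
        working = subset_reads(deduped, kept_cells, kept_genes)
        manifest.counts["cells_kept"] = len(kept_cells)
        manifest.counts["genes_kept"] = len(kept_genes)
        manifest.counts["reads_after_qc"] = len(working)
        if done("qc"):
            return _finish(result, manifest, manifest_path)

        # --- peak calling ----------------------------------------------
        by_gene: dict[str, list] = {}
        for r in working:
            by_gene.setdefault(r.gene_id, []).append(r)
        utr_of = {u.gene_id: u for u in utrs}
        all_peaks = []
        for gene_id in sorted(by_gene):
            utr = utr_of[gene_id]
            cov = compute_utr_coverage(by_gene[gene_id], utr)
            all_peaks.extend(
                call_peaks(
                    cov, utr,
                    min_height=cfg.param("peaks", "min_height"),
                    half_width=cfg.param("peaks", "half_width"),
                    min_separation=cfg.param("peaks", "min_separation"),
                    template_sd=cfg.param("peaks", "template_sd"),
                )
            )
        write_peaks_bed(all_peaks, str(outdir / "peaks.bed"))
        clusters_present = sorted({cluster_of[r.barcode] for r in working if r.barcode in cluster_of})
        for cluster in clusters_present:
            blocks = []
            for gene_id in sorted(by_gene):
                utr = utr_of[gene_id]
                sub = [r for r in by_gene[gene_id] if cluster_of.get(r.barcode) == cluster]
                if sub:
                    blocks.append((utr.chrom, utr.utr_start, compute_utr_coverage(sub, utr)))
            write_bedgraph(blocks, str(outdir / f"coverage_{cluster}.bedgraph"))
        manifest.counts["peaks_called"] = len(all_peaks)
        result.peaks = all_peaks
        if done("peaks"):
            return _finish(result, manifest, manifest_path)

        # --- counting ---------------------------------------------------
        pc = count_reads_in_peaks(working, all_peaks, kept_cells, cluster_of)
        cc = aggregate_by_cluster(pc, clusters_present)
        manifest.counts["reads_in_peaks"] = int(pc.matrix.sum())
        manifest.counts["reads_outside_peaks"] = pc.unassigned
        if done("count"):
            result.peak_counts, result.cluster_counts = pc, cc
            return _finish(result, manifest, manifest_path)

        # --- peak filters ----------------------------------------------
        keep_cpm = cpm_filter(cc, cfg.param("filters", "cpm_threshold"),
                              cfg.param("filters", "cpm_mode"))
        genome = pyfaidx.Fasta(str(paths["genome"])) if "genome" in paths else None
        if genome is not None:
            keep_arich, removal = a_rich_filter(
                all_peaks, genome,
                window=cfg.param("filters", "a_window"),
                max_a_frac=cfg.param("filters", "a_max_frac"),
                max_a_run=cfg.param("filters", "a_max_run"),
                anchor=cfg.param("filters", "a_anchor"),
            )
        else:
            keep_arich, removal = {p.peak_id for p in all_peaks}, pd.DataFrame()
        removal.to_csv(outdir / "arich_removed.tsv", sep="\t", index=False)
        surviving = [p for p in all_peaks if p.peak_id in (keep_cpm & keep_arich)]
        final_ids = drop_single_peak_genes(surviving)
        pc_f = subset_peak_counts(pc, final_ids)
        cc_f = aggregate_by_cluster(pc_f, clusters_present)
        write_mtx_triplet(pc_f, outdir)
        pd.DataFrame(cc_f.cpm, index=cc_f.peak_ids, columns=cc_f.clusters).to_csv(
            outdir / "cluster_cpm.tsv", sep="\t", index_label="peak_id"
        )
        manifest.counts["peaks_after_cpm"] = len(keep_cpm)
        manifest.counts["peaks_after_arich"] = len(keep_arich)
        manifest.counts["peaks_final"] = len(pc_f.peaks)
        result.peak_counts, result.cluster_counts = pc_f, cc_f
        if done("filter"):
            return _finish(result, manifest, manifest_path)

        # --- per-cell PUI ----------------------------------------------
        pui = mean_proximal_pui(
            pc_f, cfg.param("pui", "mode"), cfg.param("pui", "min_genes_per_cell")
        )
        pui.to_csv(outdir / "cell_pui.tsv", sep="\t", index=False)
        manifest.counts["cells_with_pui"] = len(pui)
        result.pui = pui
        if done("pui"):
            return _finish(result, manifest, manifest_path)

        # --- differential APA ------------------------------------------
        if not cfg.groups or not cfg.groups[0] or not cfg.groups[1]:
            logger.warning("no comparison groups configured; differential APA skipped")
            manifest.counts["genes_tested"] = 0
        else:
            group_a, group_b = cfg.groups
            alpha = cfg.param("test", "alpha")
            tests = diff_apa_all(cc_f, group_a, group_b, alpha)
            tests.to_csv(outdir / "apa_tests.tsv", sep="\t", index=False)
            summary = classify_events(tests, alpha)
            bc_cluster = pd.Series({bc: cluster_of.get(bc) for bc in pui["barcode"]})
            x = pui.loc[bc_cluster.reindex(pui["barcode"]).isin(group_a).to_numpy(),
                        "mean_proximal_pui"].to_numpy()
            y = pui.loc[bc_cluster.reindex(pui["barcode"]).isin(group_b).to_numpy(),
                        "mean_proximal_pui"].to_numpy()
            comparison = None
            if len(x) and len(y):
                w = wilcoxon_rank_sum(x, y)
                comparison = pd.DataFrame(
                    [{
                        "group_a": "+".join(group_a), "group_b": "+".join(group_b),
                        "n_a": len(x), "n_b": len(y),
                        "median_pui_a": float(np.median(x)), "median_pui_b": float(np.median(y)),
                        "u_statistic": w.u_statistic, "z": w.z, "p_two_sided": w.p_two_sided,
                    }]
                )
                comparison.to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)
            manifest.counts["genes_tested"] = int(tests["call"].ne("untested").sum())
            manifest.counts["genes_shortened"] = summary["n_shortened"]
            manifest.counts["genes_lengthened"] = summary["n_lengthened"]
            result.tests, result.summary, result.group_comparison = tests, summary, comparison
        done("diffapa")
        return _finish(result, manifest, manifest_path)
    except Exception:
        applicable = STAGES if cfg.sim is not None else STAGES[1:]
        pending = [s for s in applicable if s not in manifest.completed_stages]
        manifest.failed_stage = pending[0] if pending else None
        manifest.write(manifest_path)
        raise


def _finish(result: PipelineResult, manifest: RunManifest, manifest_path: Path) -> PipelineResult:
    outdir = manifest_path.parent
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json" and path.suffix != ".fai":
            manifest.checksums[str(path.relative_to(outdir))] = _sha256(path)
    manifest.write(manifest_path)
    return result
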