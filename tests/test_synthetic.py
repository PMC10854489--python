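"""Generator behaviour: determinism, planted signal, duplicates, artifacts."""

import numpy as np
import pytest
import scipy.stats

from sc3apa.synthetic import (
    ARTIFACT_RUN_LENGTH,
    GeneModel,
    SimConfig,
    SimConfigError,
    codes_to_seq,
    inject_internal_priming,
    inject_pcr_duplicates,
    read_truth,
    simulate,
    simulate_dataset,
    simulate_gene_reads,
)
from sc3apa.peaks import UtrModel


def tiny_config(**kw):
    defaults = dict(
        n_genes=4, n_clusters=2, cells_per_cluster=10,
        reads_per_gene_per_cell=3.0, dup_rate=0.0,
        internal_priming_rate=0.0, seed=5,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def plus_gene(utr_start=1000, utr_length=1000, pas=(1200, 1500)):
    utr = UtrModel(gene_id="g+", chrom="c", strand="+",
                   utr_start=utr_start, utr_end=utr_start + utr_length)
    return GeneModel(utr=utr, pas_positions=pas)


def minus_gene():
    utr = UtrModel(gene_id="g-", chrom="c", strand="-", utr_start=1000, utr_end=2000)
    return GeneModel(utr=utr, pas_positions=(1799, 1499))


class TestSimConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("dup_rate", 1.0),
            ("dup_rate", -0.1),
            ("internal_priming_rate", 1.5),
            ("default_proximal_usage", 2.0),
            ("pas_per_gene", 4),
            ("n_genes", 0),
            ("utr_length", 200),
            ("fragment_offset_sd", 0.0),
            ("reads_per_gene_per_cell", -1.0),
        ],
    )
    def test_invalid_field_raises_naming_it(self, field, value):
        with pytest.raises(SimConfigError, match=field.split("_")[0]):
            tiny_config(**{field: value})

    def test_invalid_usage_entry(self):
        with pytest.raises(SimConfigError, match="proximal_usage"):
            tiny_config(proximal_usage={("gene0001", "cluster1"): 1.7})


class TestDeterminismAndBundle:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = tiny_config(dup_rate=0.3, internal_priming_rate=0.5)
        p1 = simulate_dataset(cfg, tmp_path / "a")
        p2 = simulate_dataset(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        p1 = simulate_dataset(tiny_config(seed=1), tmp_path / "a")
        p2 = simulate_dataset(tiny_config(seed=2), tmp_path / "b")
        assert p1["sam"].read_bytes() != p2["sam"].read_bytes()

    def test_adding_genes_preserves_existing_gene_reads(self):
        small = simulate(tiny_config(n_genes=3))
        large = simulate(tiny_config(n_genes=4))
        keep = {g.gene_id for g in small.genes}
        small_reads = sorted(
            (r.gene_id, r.start, r.end, r.barcode, r.umi) for r in small.reads
        )
        large_reads = sorted(
            (r.gene_id, r.start, r.end, r.barcode, r.umi)
            for r in large.reads if r.gene_id in keep
        )
        assert small_reads == large_reads

    def test_truth_round_trips(self, tmp_path):
        cfg = tiny_config(internal_priming_rate=0.5)
        paths = simulate_dataset(cfg, tmp_path)
        truth = read_truth(str(paths["truth_genes"]), str(paths["truth_usage"]))
        ds = simulate(cfg)
        assert truth.genes.astype(str).equals(ds.truth.genes.astype(str))
        assert np.allclose(truth.usage["pi"], ds.truth.usage["pi"])

    def test_reads_lie_within_utr_and_match_strand(self):
        ds = simulate(tiny_config(dup_rate=0.2, internal_priming_rate=0.5))
        utr_of = {g.gene_id: g.utr for g in ds.genes}
        for r in ds.reads:
            utr = utr_of[r.gene_id]
            assert utr.utr_start <= r.start < r.end <= utr.utr_end
            assert r.strand == utr.strand
            assert r.barcode and r.umi

    def test_no_duplication_means_distinct_keys(self):
        ds = simulate(tiny_config(dup_rate=0.0))
        keys = {(r.barcode, r.umi, r.gene_id) for r in ds.reads}
        assert len(keys) == len(ds.reads)

    def test_read_conservation_against_truth(self):
        ds = simulate(tiny_config(dup_rate=0.0, internal_priming_rate=0.5))
        cluster_of = dict(zip(ds.cells["barcode"], ds.cells["cluster"]))
        observed = {}
        for r in ds.reads:
            key = (r.gene_id, cluster_of[r.barcode])
            observed[key] = observed.get(key, 0) + 1
        for row in ds.truth.usage.itertuples():
            expected = row.n_true_reads + row.n_artifact_reads
            assert observed.get((row.gene_id, row.cluster), 0) == expected


class TestGeneReads:
    def test_zero_reads_empty(self):
        rng = np.random.default_rng(0)
        assert simulate_gene_reads(plus_gene(), "c1", 0, 0.5, 30.0, rng, ["B1"]) == []

    def test_negative_reads_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="n_reads"):
            simulate_gene_reads(plus_gene(), "c1", -1, 0.5, 30.0, rng, ["B1"])

    def test_proximal_fraction_within_binomial_interval(self):
        rng = np.random.default_rng(42)
        gene = plus_gene()
        n = 10_000
        reads = simulate_gene_reads(gene, "c1", n, 0.5, 30.0, rng, ["B1"])
        # proximal choices end near PAS 1200, distal near 1500; split midway
        frac = np.mean([r.terminus < 1350 for r in reads])
        lo, hi = scipy.stats.binom.interval(0.99, n, 0.5)
        assert lo / n <= frac <= hi / n

    def test_degenerate_usage_all_proximal(self):
        rng = np.random.default_rng(1)
        gene = plus_gene()
        reads = simulate_gene_reads(gene, "c1", 500, 1.0, 30.0, rng, ["B1"])
        for r in reads:
            assert gene.pas_positions[0] - 150 <= r.terminus <= gene.pas_positions[0]

    def test_minus_strand_offsets_shift_to_higher_coordinates(self):
        rng = np.random.default_rng(2)
        gene = minus_gene()
        reads = simulate_gene_reads(gene, "c1", 500, 1.0, 30.0, rng, ["B1"])
        pas = gene.pas_positions[0]
        assert all(r.terminus >= pas for r in reads)
        assert any(r.terminus > pas for r in reads)


class TestPcrDuplicates:
    def test_rate_zero_identity(self):
        rng = np.random.default_rng(0)
        reads = simulate_gene_reads(plus_gene(), "c1", 50, 0.5, 30.0, rng, ["B1"])
        assert inject_pcr_duplicates(reads, 0.0, rng) == reads

    def test_duplicates_copy_key_and_position(self):
        rng = np.random.default_rng(3)
        reads = simulate_gene_reads(plus_gene(), "c1", 200, 0.5, 30.0, rng, ["B1", "B2"])
        out = inject_pcr_duplicates(reads, 0.5, rng)
        originals = {(r.barcode, r.umi, r.gene_id, r.start, r.end) for r in reads}
        for r in out:
            assert (r.barcode, r.umi, r.gene_id, r.start, r.end) in originals

    def test_expected_inflation(self):
        rng = np.random.default_rng(4)
        reads = simulate_gene_reads(plus_gene(), "c1", 2000, 0.5, 30.0, rng, ["B1"])
        out = inject_pcr_duplicates(reads, 0.5, rng)
        assert 1.8 * len(reads) <= len(out) <= 2.2 * len(reads)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_pcr_duplicates([], 1.0, np.random.default_rng(0))


class TestInternalPriming:
    def test_rate_zero_no_change(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 4, size=3000).astype(np.uint8)
        before = codes.copy()
        gene = inject_internal_priming(codes, plus_gene(), 0.0, rng)
        assert gene.artifact_anchors == ()
        assert np.array_equal(codes, before)

    def test_rate_one_plants_a_rich_run_clear_of_pas(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 4, size=3000).astype(np.uint8)
        gene = inject_internal_priming(codes, plus_gene(), 1.0, rng)
        assert len(gene.artifact_anchors) == 1
        anchor = gene.artifact_anchors[0]
        for pas in gene.pas_positions:
            assert abs(anchor - pas) >= 150
        window = codes_to_seq(codes[anchor + 1 : anchor + 21])
        assert window.count("A") / len(window) >= 0.75

    def test_minus_strand_run_is_t_on_reference(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 4, size=3000).astype(np.uint8)
        gene = inject_internal_priming(codes, minus_gene(), 1.0, rng)
        anchor = gene.artifact_anchors[0]
        window = codes_to_seq(codes[anchor - ARTIFACT_RUN_LENGTH : anchor])
        assert window == "T" * ARTIFACT_RUN_LENGTH

    def test_short_utr_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 4, size=2000).astype(np.uint8)
        utr = UtrModel(gene_id="tiny", chrom="c", strand="+", utr_start=500, utr_end=830)
        gene = GeneModel(utr=utr, pas_positions=(660,))
        with caplog.at_level("WARNING"):
            out = inject_internal_priming(codes, gene, 1.0, rng)
        assert out.artifact_anchors == ()
        assert any("tiny" in rec.message for rec in caplog.records)
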