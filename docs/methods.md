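# Methods

## Overview

`sc3apa` quantifies 3′UTR alternative polyadenylation from 3′-biased
single-cell RNA-seq. The observable is the genomic position of each read's
strand-aware 3′ terminus: for a transcript cleaved at a polyadenylation
site (PAS), library fragments end at or a short distance upstream of the
cleavage position, so the terminus density in a gene's annotated 3′UTR is a
mixture of one-sided pileups, one per used PAS. The pipeline estimates the
pileup positions (peaks), counts molecules per peak per cell, and reduces
the counts to two quantities: per-gene proximal usage (fraction of the
gene's molecules at its stop-codon-proximal peak) and a per-cell mean
proximal polyA-site usage index (PUI).

## Read model and the synthetic generator

The generator emulates aligned, tagged droplet data directly (no sequencing
or alignment simulation). Per gene and cluster, molecule counts are Poisson
with mean `reads_per_gene_per_cell × cells`; each molecule picks the
proximal PAS with probability π (the ground-truth usage; with three sites
the distal mass is split evenly) and its terminus is the PAS shifted
upstream by a **half-normal offset** (|N(0, σ)|, default σ = 30 nt,
truncated at the UTR boundary). The half-normal reproduces the sharp,
one-sided pileups that 3′-tag protocols produce; the true fragment-length
process of any particular chemistry is not modelled, so σ is an effective
spread parameter, not a measured quantity.

PCR duplication appends, per read, a geometric number of exact copies
(sharing barcode, UMI and coordinates) so that a fraction `dup_rate` of all
emitted reads are duplicates. Internal-priming artifacts are planted as an
18-nt A-run (on the read strand) written into the UTR interior at least
150 nt from every true PAS, with a sharp read pileup (σ = 5 nt — priming is
templated at the run) immediately strand-aware upstream; these reads are
real molecules and must be removed at the *peak* level, not by dedup.

Layout: one gene per UTR, non-overlapping, 50 genes per synthetic
chromosome, alternating strands; 16-nt barcodes and 10-nt UMIs as in common
droplet chemistries. Coordinates are 0-based half-open everywhere
(BED-native). Randomness is one root seed with per-gene child streams
(stable spawn keys), so extending a configuration with more genes leaves
existing genes' reads byte-identical.

What the generator does **not** contain — splicing and intronic structure,
ambient RNA, barcode errors, doublets, overlapping genes, biological
overdispersion beyond Poisson, and real PAS sequence context. Passing the
validation suite therefore demonstrates correctness of the *computational*
pipeline under a clean read model, not robustness to every artifact of real
tumor data.

## UMI deduplication and QC

Duplicates are collapsed on the exact key (barcode, gene, UMI); the
retained representative is the read with the most-3′ strand-aware terminus
(ties: smaller start, a fixed deterministic order). Exact-match collapse is
used rather than an edit-distance network: it is deterministic and
sufficient for data without simulated UMI sequencing errors; a directional
adjacency mode is a documented extension point. The key deliberately
excludes position, since 3′-biased fragments of one molecule may map a few
bases apart.

QC runs on deduplicated UMI counts, in the order dedup → cell filter → gene
filter: cells pass with `min_genes ≤ detected genes ≤ max_genes`
(defaults 200/6000) and mitochondrial fraction ≤ 0.10 (genes identified by
the configurable prefix `MT-`; a zero-count cell has the fraction defined
as 0 and fails on gene count); genes pass when detected in ≥ 3 kept cells.
The defaults target genome-wide droplet panels; synthetic runs with a few
hundred genes rescale `min_genes` in their configs, as any real analysis
would for a targeted panel.

## Peak calling

Coverage counts read 3′ termini (+ strand: interval end − 1; − strand:
interval start), not footprints — footprint coverage from a distal site
overruns proximal sites and smears adjacent pileups together.

Summits are scored with a **one-sided matched filter**: the
cross-correlation of the coverage vector with the expected half-normal
footprint (template spread `template_sd`, default 30 nt, matching the
fragment model). A raw argmax is a poor summit estimator for one-sided
pileups — at 200 reads and σ = 30 it lands within ±10 nt of the true site
only about half the time, and symmetric smoothing biases the maximum
upstream — whereas the matched filter is unbiased at the cleavage position
(empirically ±1 nt at that depth). Candidate summits are selected greedily
in decreasing score order (ties: most proximal position), each masking
`min_separation` (150 nt) around itself; a candidate is emitted only if raw
coverage within its window reaches `min_height` (5 reads at one base).
Applying the height gate after candidate selection makes the peak count
monotone non-increasing in `min_height`. Peaks span
`summit ± half_width` (100 nt) clipped to the UTR and are trimmed disjoint
by splitting overlaps at the midpoint between summits. Defaults resolve PAS
≥ 150 nt apart; all four knobs are configurable.

`min_height = 5` on per-base coverage implies a detectability floor: a
pileup with spread σ = 30 distributes ≈ 2.7% of its reads to its modal
base, so a site needs roughly ≥ 200 reads (pooled over cells) to be called
reliably. Validation scenarios are sized accordingly.

Ranking: order_index 1..k by strand-aware distance of the summit from the
stop-codon end of the UTR; index 1 is the proximal peak.

## Quantification and peak filters

A read increments the unique peak of its own gene containing its terminus;
reads in no peak are tallied as unassigned (conservation is asserted in the
manifest). Cluster CPM is `counts × 10⁶ / cluster column total`.

- **Low-count filter**: a peak is dropped only when its CPM is strictly
  below 10 in *every* cluster (kept at exactly 10.0). The max-over-clusters
  reading preserves cluster-specific peaks, which the cluster-level
  analysis needs; a summed-CPM mode is available and the choice is recorded
  in the run manifest.
- **A-rich filter**: the 20-nt window immediately 3′ of the peak summit, on
  the read strand, removes the peak when its A fraction is ≥ 0.70 or it
  contains ≥ 8 consecutive A. The window is anchored at the summit because
  the summit estimates the cleavage/priming position and internal priming
  leaves its A-stretch right there; anchoring past the peak *interval*
  (also available as `anchor="end"`) inspects sequence ~100 nt downstream
  of the priming site and misses the artifact. Thresholds are configurable
  and echoed in the manifest.

Both filters are independent peak predicates, so they commute; genes
retaining fewer than two peaks are excluded from APA statistics.

## Statistics

**Proximal usage** pools all distal peaks against the proximal one
(`k₁ / Σkᵢ`), making "shortened" monotone in proximal mass for genes with
more than two peaks; usage is undefined (and the unit excluded) at zero
total.

**Differential APA** per gene: Pearson χ² (no continuity correction) on the
k-peaks × 2-groups table of counts summed within each group; df =
(k−1)(2−1). Genes with a zero row or column margin are reported untested
rather than pseudocounted. P-values are BH-adjusted across tested genes;
a gene is called *shortened* when q < α (default 0.05) and the group-level
usage difference Δ = u(B) − u(A) is positive, *lengthened* when negative.

**Mean proximal PUI** per cell: over the cell's multi-peak genes with
defined usage, the mean of either raw usage (in [0,1]) or per-gene
z-scores across cells (default; genes with zero variance across cells are
skipped, sample sd, ddof = 1). Standardisation weights genes equally
regardless of baseline usage; both modes are exposed because per-cell usage
indices in the literature differ in this respect. Cells with fewer than
`min_genes_per_cell` (10) informative genes are omitted.

**Wilcoxon rank-sum** between group PUI distributions: midranks for ties,
U from the rank sum, z = (|U − n₁n₂/2| − ½) / σ with the tie-corrected
variance n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))], two-sided p from the normal
tail; the ½ continuity term is optional. Degenerate pooled-constant input
returns p = 1 by convention. The implementation is checked against an
independent reference to |Δp| ≤ 10⁻⁸.

## Validation scenarios and problem sizes

The operating characteristics are measured on fixed scenarios
(`sc3apa.scenarios`): summit recovery on 100 two-site genes (sites 300 nt
apart, ~250 reads/site); artifact filtering on 60 genes all carrying a
planted A-run; usage recovery on 8 genes × 2 clusters spanning π 0.2–0.8 at
~10⁴ reads per (gene, cluster) — depth at which the binomial standard error
(≤ 0.005) keeps every estimate within the ±0.02 check; differential-test
error rates on 500 null + 50 shifted genes (Δπ = +0.3) at ~400 in-peak
counts per group per gene, a depth chosen so both PAS of every gene sit
above the caller's detectability floor; PUI direction on 100 genes with
clusters of 200 cells at π 0.8 vs 0.4. The flagship cohort (300 genes,
50+10 planted events at a 5:1 imbalance) exercises the full pipeline
including duplication and artifact injection.

## Known limitations

- Gene assignment requires annotated, non-overlapping 3′UTRs; no de-novo
  UTR discovery, no multi-mapper resolution.
- Exact-match UMI collapse ignores UMI sequencing errors.
- The χ² test treats cells within a group as exchangeable; it does not
  model per-cell overdispersion or patient-level replication.
- The A-rich thresholds (20 nt / 0.70 / run 8) are field-standard values,
  configurable but not re-derived from data here.
- Peak boundary placement (half-width, midpoint splits) is heuristic;
  conclusions should rest on summit-level quantities, which is what the
  statistics consume.
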