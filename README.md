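# sc3apa

Alternative polyadenylation (APA) analysis of 3′UTRs from 3′-biased
single-cell RNA-seq.

Most droplet scRNA-seq chemistries sequence the 3′ end of each transcript,
so the read pileup in a gene's 3′UTR encodes *where* that transcript was
cleaved and polyadenylated. Genes with several polyadenylation sites (PAS)
can therefore be scored, cell by cell, for how often the **proximal** site
(closest to the stop codon) is used: high proximal usage means short
3′UTRs, which typically strips destabilising elements and raises protein
output. `sc3apa` turns barcode/UMI-tagged alignments into:

- per-gene **differential APA calls** between two cell groups
  (*shortened* / *lengthened* / not significant), and
- a per-cell **mean proximal polyA-site usage index (PUI)** summarising
  global 3′UTR shortening in each cell,

together with a seedable synthetic-data generator that plants known ground
truth (usage probabilities, PCR duplicates, internal-priming artifacts) so
every stage of the pipeline can be validated quantitatively.

## Method

For gene *g* with peaks ranked proximal→distal (index 1 = proximal) and UMI
counts *k₁ … k_m* in a unit (cell or cluster), proximal usage is

```
u_g = k₁ / Σᵢ kᵢ          (undefined when the denominator is 0)
```

The pipeline stages:

1. **Ingest & deduplicate** — primary mapped reads with CB/UB tags are
   assigned to genes by strand-matched 3′UTR overlap and collapsed to one
   molecule per (barcode, gene, UMI) key.
2. **QC** — cells kept with 200–6000 detected genes and ≤10% mitochondrial
   UMIs; genes kept when detected in ≥3 cells (all thresholds configurable).
3. **Peak calling** — coverage counts read 3′ termini; summits are located
   with a one-sided matched filter (the expected half-normal footprint of a
   cleavage site) and selected greedily with a separation mask, then ranked
   proximal→distal.
4. **Quantify & filter** — reads counted into peaks per cell; peaks below
   10 CPM in every cluster are dropped, as are peaks whose downstream
   window is A-rich on the read strand (internal-priming artifacts).
5. **Statistics** — per gene, a Pearson χ² test on the peak × group count
   table with Benjamini–Hochberg correction across genes; per cell, the
   mean (optionally z-standardised) proximal usage over its informative
   genes; group PUI distributions compared with the tie- and
   continuity-corrected Wilcoxon rank-sum test.

## Worked example

The numbered scripts under `analysis/` run a complete study on a synthetic
tumor-vs-normal cohort (300 genes × 100 cells; 50 genes planted to shorten
in tumor, 10 to lengthen, 30% PCR duplication, 10% internal-priming rate):

```
$ python analysis/01_simulate_cohort.py --seed 1
simulated 300 genes x 100 cells (seed 1)
planted ground truth: 50 shortened, 10 lengthened, 240 null genes

$ python analysis/02_dedup_and_qc.py --seed 1
358133 aligned records -> 250609 molecules (30.0% PCR duplicates removed)
cells kept: 100; genes kept: 300; reads after QC: 250609

$ python analysis/03_call_and_filter_peaks.py --seed 1
peaks called: 627 (250439 reads assigned, 170 outside peaks)
after CPM filter: 627; after A-rich filter: 599; final (multi-peak genes): 598
A-rich filter removed 28 peaks; 27 genes carry a planted artifact

$ python analysis/04_differential_apa.py --seed 1
genes tested: 299
shortened in tumor: 53 (50 planted); lengthened: 9 (10 planted); ratio 5.89
mean proximal PUI, tumor vs normal: median shift +0.173, Wilcoxon z=8.41, p=3.97e-17
```

The recovered event counts match the planted truth up to the test's
expected error rates, the shortened:lengthened ratio reflects the planted
5:1 imbalance, and the tumor cells show the planted upward shift in mean
proximal PUI. `analysis/05_operating_characteristics.py` measures summit
recovery, artifact-filter sensitivity/specificity, usage accuracy and the
differential test's false-positive rate and power against ground truth.

The same pipeline runs from a single config:

```
sc3apa run --config run.yaml        # or per stage: simulate, dedup, qc,
                                    # callpeaks, count, filter, pui, diffapa
```

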