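# asarscan

Toolkit and analysis pipeline for screening RNA-seq coverage and cytogenetic
data for **ASAR-like loci** — very long intergenic noncoding RNA (vlincRNA)
genes whose disruption delays the replication timing of their whole
chromosome in *cis*. ASAR ("ASynchronous replication and Autosomal RNA")
transcripts share a distinctive signature: they are >50 kb of contiguously
transcribed, nonspliced sequence not associated with protein-coding genes,
strongly retained in the nucleus, expressed from a single homolog chosen at
random (programmed random monoallelic expression, PRME), replicated
asynchronously in coordination with other monoallelic loci on the same
chromosome, and unusually rich in LINE-1 (L1) retrotransposon sequence —
autosomes average ~13% L1 while ASAR candidate loci reach two times that or
more.

The package is written for genomics researchers who want to run this screen
on coverage tracks and cytogenetic count tables, and ships a synthetic-data
generator that emulates every input with known ground truth, so the entire
pipeline is testable on a laptop with no downloads.

## What it computes

- **Transcribed-domain calling** (`asarscan.domains`): maximal runs of
  per-base depth ≥ *c*, bridging sub-threshold gaps ≤ *g*, kept when the run
  length ≥ *L*min (default 50 kb); domains overlapping protein-coding gene
  bodies are removed.
- **L1 composition and enrichment** (`asarscan.repeats`): for a domain
  spanning *L* bases, the L1 fraction is |union of L1 intervals ∩ domain| / L.
  The null assembles random intronic sequence of total length *L* (whole
  introns drawn uniformly with replacement, last intron trimmed at a random
  offset), records the L1 fraction of each of *n* replicates, fits a Beta(α,β)
  by method of moments (α = m·c, β = (1−m)·c with c = m(1−m)/v − 1), and
  reports the upper-tail p-value P(X ≥ x̂) of the fitted beta together with
  the empirical rank p-value (r+1)/(n+1).
- **Allelic state** (`asarscan.allelic`): a DNA-heterozygous SNP with RNA
  major-allele fraction ≥ 0.95 at depth ≥ 20 is monoallelic; the expressed
  homolog is resolved against mono-chromosomal hybrid genotypes; locus calls
  require agreement across SNPs. Nuclear retention is the
  nuclear/cytoplasmic fold ratio on a common normalized scale.
- **Cytogenetic coordination** (`asarscan.cyto`): per-cell FISH signal
  summaries and an exact two-sided binomial test of the cis-configuration
  count against p = 0.5 (coordinated random monoallelic expression vs the
  ~50% expectation under imprinting); ReTiSH 5 h / 14 h BrdU hybridization
  patterns classify each allele as early- or late-replicating, with
  centromere QC, and asynchronous cells are scored cis/trans.
- **Replication timing** (`asarscan.timing`): per-homolog BrdU incorporation
  from metaphase images (total = mean pixel intensity × area ≡ pixel sum),
  homologs identified by the centromere-size polymorphism (larger = 6A),
  per-cell ratio 6B/6A, and a tie-corrected Kruskal–Wallis comparison of
  genotype groups.
- **The screen** (`asarscan.screen`): conjunction of named flags
  (length, noncoding, nuclear ≥ 5×, monoallelic, L1 p < 0.05) over every
  called domain.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1). `01_simulate_dataset.py` writes a 5 Mb chromosome-6-like
annotation whose cluster of six long noncoding domains contains one
expressed, L1-rich, ~185 kb focal domain:

```text
$ python analysis/02_call_domains.py
1 domain(s) >= 50 kb called:
chrom   start     end  length  mean_depth  n_gaps_bridged
 chr6 1640000 1825000  185000        20.0               4

$ python analysis/03_l1_enrichment.py
chr6:1640000-1825000: L1 fraction 0.2914 vs intronic null mean 0.1216 -> p_beta=7.29e-06 (enriched)

$ python analysis/04_allelic_state.py
locus: monoallelic, expressed from homolog B (3 informative SNPs)

$ python analysis/06_replication_timing.py
intact: median 6B/6A ratio 1.000 (planted 1.0, n=12)
del_silent_6A: median 6B/6A ratio 1.001 (planted 1.0, n=12)
del_expressed_6B: median 6B/6A ratio 2.002 (planted 2.0, n=12)
Kruskal-Wallis: H=23.605, df=2, p=7.485e-06
```

Of the six domains only the expressed one is called; its L1 content (29% vs
the ~12% intronic background) is significantly enriched under the
intron-resampling beta null; the RNA is monoallelic and phased to homolog B;
and deleting the expressed allele (planted as a 2× BrdU ratio) separates
cleanly from the intact and silent-allele-deleted clones. The same stages
are available as a CLI (`asarscan simulate|detect|repeats|allelic|fish|
retish|brdu|screen`), and `analysis/07_candidate_screen.py` runs the full
conjunction screen (one candidate flagged).

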