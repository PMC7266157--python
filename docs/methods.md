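# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open; 1-based closed conventions
(GFF3/GTF, RepeatMasker `.out`) are converted only at the format boundary.
Chromosome names are matched exactly (no silent `chr` stripping). Interval
union, subtraction and overlap are computed on merged (disjoint) interval
lists, so overlapping repeat fragments are never double counted; abutting
intervals merge. L1 membership of a RepeatMasker class/family token is
"class `LINE` and family starting with `L1`" (or a bare `L1*` label); the
predicate is an argument wherever it matters.

## Transcribed-domain calling

vlincRNA-style loci are operationalized as maximal runs of positions with
depth ≥ `min_cov`, after bridging sub-threshold gaps ≤ `max_gap`, retained
at length ≥ `min_len` = 50,000 bases (the defining >50 kb contiguity
criterion). No public threshold exists for the depth cutoff, so the default
adapts to the library: 0.25 × the track's nonzero median depth with an
absolute floor of 2. Bridged bases count toward the genomic span (length is
the genomic extent of the transcript) but not toward the mean-depth
numerator, so reported depth reflects observed signal; the denominator is
the full span. Stranded tracks are called per strand; unstranded tracks
yield unstranded domains. "Not associated with protein-coding genes" is
enforced as zero tolerated overlap with protein-coding **gene bodies** on
either strand — stricter than exon-only overlap and the safer choice for
candidacy; the tolerance is a parameter.

## L1 enrichment: the intron-resampling beta null

The question is whether a domain's L1 fraction exceeds what comparable
intronic sequence carries. The sampling universe is the exon-free interior
of gene bodies: per-gene gaps between consecutive exons, merged across
genes, with any exon-overlapping bases subtracted (subtraction, rather than
discarding whole overlapping introns, preserves intronic bases and keeps
the universe well-defined for overlapping isoforms). Each replicate draws
whole introns uniformly with replacement until the accumulated length
reaches the domain span L (the genomic span, since the transcript is
unspliced), trimming the final intron to the exact remainder from a
uniformly chosen in-intron start; the statistic is the L1-covered fraction
of the assembled sequence. Introns are sorted canonically before sampling,
so results depend only on the seed, not input order. Defaults: 10,000
replicates, mandatory seed.

A Beta(α, β) is fitted to the replicate fractions by method of moments
(c = m(1−m)/v − 1; α = mc; β = (1−m)c), and the reported p-value is the
fitted upper tail at the observed fraction; the empirical rank p-value
(r+1)/(n+1) is always reported alongside, and is the fallback when the fit
is degenerate (all replicates equal). **Known limitation:** the null is a
sum of ~L/1 kb intron contributions and is slightly skew relative to the
beta family, so the fitted tail carries a model error of up to ~0.02 in
CDF; at 10⁴ replicates this exceeds the Monte-Carlo error of the empirical
estimate at central quantiles. Both p-values are reported precisely so this
approximation is visible; conclusions should rest on the empirical p when
the two disagree materially.

## Allelic state and homolog assignment

Chromatogram-style evidence for monoallelic expression is categorical, so
the quantitative proxy is a threshold: a DNA-heterozygous SNP is
monoallelic when its RNA major-allele fraction is ≥ 0.95 (boundary
inclusive) at depth ≥ 20, biallelic below, indeterminate under-depth. No
per-SNP statistical test is applied by default: at chromatogram-like depth
the binomial null is untestable, and the threshold mirrors the categorical
read-out. The expressed homolog comes from mono-chromosomal hybrid
genotypes (each hybrid carries one homolog, so its genotype phases every
informative SNP); a major allele matching exactly one homolog's allele
assigns it. Locus calls require every informative SNP monoallelic with
agreeing homologs; any biallelic SNP makes the locus biallelic; conflicting
homologs make it indeterminate. Homolog labels A/B are arbitrary per sample
and fixed by the hybrid table. Nuclear retention is
(nuclear + ε)/(cytoplasmic + ε) on a common normalized scale, with ε the
smallest observable unit (one read per base over the locus in the pipeline);
both levels zero is reported as not-expressed, not as a ratio.

## Cytogenetic coordination

Two loci both subject to programmed random monoallelic expression are
expressed from the same homolog in (nearly) all cells of a non-clonal
population when coordinated; an imprinted locus paired with a random one
lands on the same homolog in ~50% of cells. Cells with both probes showing
exactly one signal and a resolved configuration enter an exact two-sided
binomial test of the cis count against p = 0.5 (minimum-likelihood
summation); classification at α = 0.01. Cells with two signals for either
probe (biallelic-appearing, a few percent in practice) are excluded and
tallied separately.

ReTiSH: the 14 h BrdU pulse spans all of S phase and must label both
homologs at every locus; centromeric heterochromatin is late-replicating,
so the centromere control must label both homologs at both time points —
violations are QC failures. The 5 h pulse covers only late S, so a single
5 h-positive homolog marks the **late**-replicating allele (asynchronous);
both positive is synchronous-late, neither synchronous-early. Cells with
both loci asynchronous are scored cis (late alleles on the same homolog) or
trans.

## BrdU replication timing

Per-homolog incorporation is total fluorescence = mean pixel intensity ×
pixel area, which is identically the pixel sum over the chromosome mask
(asserted as an invariant). Measurements enter either as pre-extracted
workstation tables (area + mean intensities per homolog; assumed
background-corrected) or from image triplets: Otsu threshold on DAPI,
connected components above a minimum area (50 px), homologs assigned by
integrated in-mask centromere signal (larger = 6A, the larger-centromere
chromosome) with a 10% indistinguishability margin below which the cell is
excluded, and per-image median background subtraction of non-chromosome
BrdU pixels (on by default for images, off for tables). The per-cell
statistic is total-BrdU(6B)/total-BrdU(6A). Groups of 8–12 cells per clone
(the scale of such experiments, and the default simulation size) are
compared by the Kruskal–Wallis test with mid-ranks and tie correction
1 − Σ(t³−t)/(N³−N), p from the χ² upper tail with k−1 df (computed via
scipy; an all-identical input degenerates to H = 0, p = 1). The χ²
approximation is used at all n for comparability; a permutation oracle
backs it in the test suite.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline is meant to detect:

- **Annotation**: non-overlapping gene bodies (log-normal length, median
  100 kb) covering ~45% of each chromosome, ~8 exons per gene (~200 bp);
  L1 copies placed by sequential uniform sampling with rejection of
  intra-family overlap, log-normal lengths (median 1 kb), uniform strand,
  to a per-chromosome target fraction — 0.13 on autosomes, 0.27 on chrX.
  Planted domains are kept gene-free and topped up to their own L1 target
  (0.29 for the focal domain) with a 0.7 bias toward the strand antisense
  to transcription, reflecting the antisense-L1 hallmark of these RNAs.
- **Coverage**: a six-domain cluster in which a single ~185 kb focal domain
  is expressed (depth 20, Poisson noise available) and five decoys are
  silent; background transcription defaults to 0 so exact cases stay exact.
- **Allele counts**: monoallelic loci leak a Binomial(depth, error) minor
  count; biallelic loci draw Binomial(depth, 0.5); hybrid genotypes and
  truth labels are emitted alongside.
- **FISH/ReTiSH tables**: coordinated modes place probes on the same or
  opposite homolog before noise; detection (default 0.9), miscall (0.02)
  and biallelic-appearance (0.02) rates generate realistic zero-signal and
  excluded cells; ReTiSH constructions are exact by design.
- **Images**: two equal-area axis-aligned ellipses with uniform DAPI, BrdU
  density ratio planted, one strictly larger centromere blob (6A side
  randomized per seed), Gaussian noise (default 2.5 ≈ 5% of the BrdU
  signal), truth masks returned.

One master seed fans out to per-simulator child streams by fixed offsets,
so every simulator is a pure function of (parameters, seed) and each output
can be regenerated from the manifest.

What the generator does **not** emulate: sequence-level repeat content and
subfamily structure, mapping bias at SNPs, regional (isochore-scale)
variation in L1 density, splice structure, realistic chromosome morphology
or banding, and optical artefacts. Consequently, passing tests demonstrate
correctness of the measurement and inference machinery under the stated
conditions, not performance on real microscopy or alignment artefacts. In
particular, the uniform placement of L1 makes the intron null tighter than
a real genome's regionally heterogeneous L1 landscape, so enrichment
p-values on synthetic data are smaller than would be observed against a
real annotation at the same observed fraction.

## Problem sizes

Default analyses run on a 5 Mb synthetic chromosome, 10⁴ null replicates,
hundreds of cells per cytogenetic table, and 8–12 cells per imaging group —
sizes chosen so the complete pipeline and its test suite execute in minutes
on one CPU while keeping every statistical check well-powered.
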