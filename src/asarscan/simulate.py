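"""Synthetic data with the statistical structure the screen assumes.

The generator emulates the study conditions end to end: a chromosome-6-like
sequence context with genes, introns and LINE-1 repeats at ~13% of autosomal
bases (~27% on chrX), a cluster of six long transcribed domains of which one
focal ~185 kb domain is expressed and L1-rich (~29%), allele counts at
heterozygous SNPs phased to two homologs via mono-chromosomal hybrid
genotypes, per-cell FISH and ReTiSH tables, and two-channel metaphase images
with planted BrdU homolog ratios.  Truth labels are always returned next to
the observations, and every simulator is a pure function of its parameters
and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .allelic import AlleleCountRecord
from .coverage import CoverageTrack
from .cyto import FishCellRecord, ReTiSHRecord
from .intervals import Feature, FeatureSet, GenomicInterval

__all__ = [
    "DomainSpec",
    "SimulationConfig",
    "BrdUImage",
    "child_rng",
    "simulate_annotation",
    "simulate_coverage",
    "simulate_allele_counts",
    "simulate_fish_table",
    "simulate_retish_table",
    "simulate_brdu_image",
    "default_domain_cluster",
]

# study-condition defaults: autosomal L1 ~13%, chrX ~27%, focal domain ~185 kb at
# ~29% L1, inside a cluster of six domains of which only the focal one is
# expressed, nuclear enrichment >100x
L1_AUTOSOME_DENSITY = 0.13
L1_CHRX_DENSITY = 0.27
FOCAL_DOMAIN_LENGTH = 185_000
FOCAL_DOMAIN_L1_FRACTION = 0.29
FOCAL_ANTISENSE_FRACTION = 0.7


def child_rng(master_seed: int, offset: int) -> np.random.Generator:
    """Deterministic per-simulator stream: one master seed fans out to child
    streams by fixed integer offsets."""
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(offset,)))


@dataclass(frozen=True)
class DomainSpec:
    """One planted transcribed domain."""

    interval: GenomicInterval
    depth: float
    l1_target: float | None = None
    antisense_fraction: float = FOCAL_ANTISENSE_FRACTION
    name: str = ""


def default_domain_cluster(
    chrom: str = "chr6",
    cluster_start: int = 1_000_000,
    focal_depth: float = 20.0,
) -> list[DomainSpec]:
    """Six-domain cluster within a 1 Mb window, one expressed focal domain.

    Mirrors a locus where six long noncoding domains are annotated but only
    one (~185 kb, L1-rich) is transcribed in the assayed cell line; the other
    five get depth 0 and background L1 content.
    """
    lengths = [60_000, 75_000, 55_000, 80_000, 70_000, FOCAL_DOMAIN_LENGTH]
    gap = 60_000
    specs = []
    pos = cluster_start
    for i, length in enumerate(lengths):
        focal = i == len(lengths) - 1
        specs.append(
            DomainSpec(
                interval=GenomicInterval(chrom, pos, pos + length, "+"),
                depth=focal_depth if focal else 0.0,
                l1_target=FOCAL_DOMAIN_L1_FRACTION if focal else None,
                name=f"domain_{i + 1}" + ("_focal" if focal else ""),
            )
        )
        pos += length + gap
    return specs


@dataclass
class SimulationConfig:
    """Study-condition defaults for the whole synthetic pipeline."""

    genome: dict[str, int] = field(default_factory=lambda: {"chr6": 5_000_000})
    gene_fraction: float = 0.45  # fraction of each chromosome under gene bodies
    mean_gene_length: int = 100_000
    exons_per_gene: int = 8
    mean_exon_length: int = 200
    l1_density: dict[str, float] = field(default_factory=dict)  # per-chrom override
    repeat_length_median: int = 1_000
    repeat_length_sigma: float = 0.7
    domains: list[DomainSpec] = field(default_factory=default_domain_cluster)
    background_rate: float = 0.0
    noise_model: str = "none"  # none | poisson
    n_snps: int = 3
    snp_depth: int = 50
    snp_error_rate: float = 0.01
    fish_detection_rate: float = 0.9
    fish_miscall_rate: float = 0.02
    fish_biallelic_rate: float = 0.02
    nuclear_depth: float = 20.0
    cytoplasmic_depth: float = 0.1
    image_shape: tuple[int, int] = (128, 256)
    image_noise_sd: float = 2.5
    master_seed: int = 0

    def chrom_l1_density(self, chrom: str) -> float:
        if chrom in self.l1_density:
            return self.l1_density[chrom]
        return L1_CHRX_DENSITY if chrom in {"chrX", "X"} else L1_AUTOSOME_DENSITY


# --------------------------------------------------------------------------
# annotation


def _place_genes(
    config: SimulationConfig,
    chrom: str,
    size: int,
    forbidden: list[GenomicInterval],
    rng: np.random.Generator,
) -> list[Feature]:
    """Non-overlapping gene bodies with exons; planted-domain space is kept
    gene-free so the focal domains stay intergenic."""
    features: list[Feature] = []
    target = config.gene_fraction * size
    placed = 0
    cursor = int(rng.integers(0, 50_000))
    gi = 0
    while placed < target:
        length = int(
            np.clip(rng.lognormal(np.log(config.mean_gene_length), 0.5), 20_000, size // 4)
        )
        start, end = cursor, cursor + length
        if end >= size:
            break
        body = GenomicInterval(chrom, start, end)
        if any(body.overlaps(f) for f in forbidden):
            # jump past the blocking domain
            blocker = max(f.end for f in forbidden if body.overlaps(f))
            cursor = blocker + int(rng.integers(5_000, 30_000))
            continue
        gi += 1
        name = f"{chrom}_gene{gi}"
        biotype = "protein_coding" if rng.random() < 0.8 else "lincRNA"
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(Feature(GenomicInterval(chrom, start, end, strand), "gene", biotype, name))
        # exons: one per roughly equal block, at a random in-block offset
        k = max(2, int(rng.poisson(config.exons_per_gene)))
        block = length // k
        for j in range(k):
            elen = int(np.clip(rng.lognormal(np.log(config.mean_exon_length), 0.5), 50, max(51, block - 1)))
            off = int(rng.integers(0, max(1, block - elen)))
            es = start + j * block + off
            features.append(
                Feature(GenomicInterval(chrom, es, min(es + elen, end), strand), "exon", biotype, name)
            )
        placed += length
        cursor = end + int(rng.integers(5_000, 40_000))
    return features


def _fill_l1(
    chrom: str,
    region: tuple[int, int],
    occupancy: np.ndarray,
    target_fraction: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    antisense_fraction: float | None = None,
    domain_strand: str = "+",
) -> list[Feature]:
    """Place L1 copies uniformly (rejecting intra-family overlap) within a
    region until its covered fraction reaches the target."""
    lo, hi = region
    span = hi - lo
    features: list[Feature] = []
    covered = int(occupancy[lo:hi].sum())
    attempts = 0
    max_attempts = 200_000
    while covered / span < target_fraction and attempts < max_attempts:
        attempts += 1
        length = int(
            np.clip(
                rng.lognormal(np.log(config.repeat_length_median), config.repeat_length_sigma),
                100,
                8_000,
            )
        )
        if length >= span:
            continue
        start = lo + int(rng.integers(0, span - length))
        if occupancy[start : start + length].any():
            continue
        occupancy[start : start + length] = True
        covered += length
        if antisense_fraction is None:
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            anti = "-" if domain_strand == "+" else "+"
            strand = anti if rng.random() < antisense_fraction else domain_strand
        features.append(
            Feature(GenomicInterval(chrom, start, start + length, strand), "repeat", "LINE/L1", "L1")
        )
    if covered / span < target_fraction:
        raise ValueError(
            f"could not reach L1 fraction {target_fraction} on {chrom}[{lo}:{hi}] "
            f"(reached {covered / span:.3f}); density may be infeasible"
        )
    return features


def simulate_annotation(config: SimulationConfig, seed: int | None = None) -> FeatureSet:
    """Genes with exons plus L1 repeats at the configured densities.

    Background L1 is placed uniformly chromosome-wide; each planted domain
    with an ``l1_target`` is then topped up to its own fraction, with a bias
    toward the strand antisense to transcription.  Densities must be feasible
    (< 1 after accounting for placement granularity).
    """
    for chrom in config.genome:
        d = config.chrom_l1_density(chrom)
        if not 0.0 <= d < 0.95:
            raise ValueError(f"infeasible L1 density {d} on {chrom}")
    master = config.master_seed if seed is None else seed
    features: list[Feature] = []
    for ci, (chrom, size) in enumerate(sorted(config.genome.items())):
        rng = child_rng(master, 100 + ci)
        domains_here = [d.interval for d in config.domains if d.interval.chrom == chrom]
        features.extend(_place_genes(config, chrom, size, domains_here, rng))
        occupancy = np.zeros(size, dtype=bool)
        density = config.chrom_l1_density(chrom)
        if density > 0:
            features.extend(_fill_l1(chrom, (0, size), occupancy, density, config, rng))
        for spec in config.domains:
            if spec.interval.chrom != chrom or spec.l1_target is None:
                continue
            features.extend(
                _fill_l1(
                    chrom,
                    (spec.interval.start, spec.interval.end),
                    occupancy,
                    spec.l1_target,
                    config,
                    rng,
                    antisense_fraction=spec.antisense_fraction,
                    domain_strand=spec.interval.strand if spec.interval.strand in "+-" else "+",
                )
            )
    features.sort(key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end, f.kind))
    return FeatureSet(features, dict(config.genome))


# --------------------------------------------------------------------------
# coverage


def simulate_coverage(
    domains: list[DomainSpec],
    genome: dict[str, int],
    noise_model: str = "none",
    background_rate: float = 0.0,
    seed: int = 0,
    strand: str = ".",
) -> CoverageTrack:
    """Per-base depth: the target depth inside each planted domain (Poisson
    around it when ``noise_model='poisson'``), a low background rate outside,
    zero elsewhere."""
    if noise_model not in {"none", "poisson"}:
        raise ValueError("noise_model must be 'none' or 'poisson'")
    for spec in domains:
        if spec.depth < 0:
            raise ValueError("domain depth must be >= 0")
    by_strand_chrom: dict[tuple[str, str], list[DomainSpec]] = {}
    for spec in domains:
        key = (spec.interval.strand, spec.interval.chrom)
        for other in by_strand_chrom.get(key, []):
            if spec.interval.overlaps(other.interval):
                raise ValueError(
                    f"overlapping domains on same strand: {spec.name} vs {other.name}"
                )
        by_strand_chrom.setdefault(key, []).append(spec)
    rng = child_rng(seed, 200)
    data: dict[str, np.ndarray] = {}
    for chrom, size in sorted(genome.items()):
        if background_rate > 0:
            vec = (
                rng.poisson(background_rate, size).astype(float)
                if noise_model == "poisson"
                else np.full(size, float(background_rate))
            )
        else:
            vec = np.zeros(size)
        for spec in domains:
            if spec.interval.chrom != chrom:
                continue
            s, e = spec.interval.start, spec.interval.end
            if noise_model == "poisson":
                vec[s:e] = rng.poisson(spec.depth, e - s)
            else:
                vec[s:e] = spec.depth
        data[chrom] = vec
    return CoverageTrack(data, strand=strand)


# --------------------------------------------------------------------------
# allele counts

_BASES = np.array(list("ACGT"))


def simulate_allele_counts(
    mode: str,
    n_snps: int = 3,
    depth: int = 50,
    error_rate: float = 0.01,
    seed: int = 0,
    chrom: str = "chr6",
    region: tuple[int, int] = (1_640_000, 1_825_000),
    expressed_homolog: str = "B",
) -> tuple[list[AlleleCountRecord], dict[str, tuple[str, str]], dict]:
    """RNA allele counts at heterozygous SNPs plus the hybrid phasing table.

    monoallelic: all reads come from ``expressed_homolog``'s allele except a
    Binomial(depth, error_rate) sequencing-error leak to the other allele.
    biallelic: the reference count is Binomial(depth, 0.5).  "imprinted" is
    an alias of monoallelic (one fixed expressed homolog).  Truth (mode and
    expressed homolog per SNP) is returned alongside.
    """
    if mode not in {"monoallelic", "biallelic", "imprinted"}:
        raise ValueError(f"unknown mode {mode!r}")
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = child_rng(seed, 300)
    positions = np.sort(rng.choice(np.arange(region[0], region[1]), size=n_snps, replace=False))
    records: list[AlleleCountRecord] = []
    hybrids: dict[str, tuple[str, str]] = {}
    for i, pos in enumerate(positions):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        # which homolog carries the ref allele
        a_allele, b_allele = (ref, alt) if rng.random() < 0.5 else (alt, ref)
        snp_id = f"snp{i + 1}"
        hybrids[snp_id] = (str(a_allele), str(b_allele))
        if mode in {"monoallelic", "imprinted"}:
            expressed = a_allele if expressed_homolog == "A" else b_allele
            errors = int(rng.binomial(depth, error_rate))
            exp_count, other_count = depth - errors, errors
            ref_count = exp_count if expressed == ref else other_count
        else:
            ref_count = int(rng.binomial(depth, 0.5))
        records.append(
            AlleleCountRecord(
                snp_id=snp_id,
                position=GenomicInterval(chrom, int(pos), int(pos) + 1),
                ref_base=str(ref),
                alt_base=str(alt),
                dna_genotype="het",
                rna_ref_count=ref_count,
                rna_alt_count=depth - ref_count,
            )
        )
    truth = {
        "mode": mode,
        "expressed_homolog": expressed_homolog if mode != "biallelic" else None,
        "seed": seed,
    }
    return records, hybrids, truth


# --------------------------------------------------------------------------
# FISH / ReTiSH tables

FISH_MODES = {"coordinated_cis", "coordinated_trans", "independent", "imprinted"}


def simulate_fish_table(
    mode: str,
    n_cells: int,
    detection_rate: float = 1.0,
    miscall_rate: float = 0.0,
    biallelic_rate: float = 0.0,
    seed: int = 0,
    probes: tuple[str, str] = ("focal", "control"),
) -> tuple[list[FishCellRecord], dict]:
    """Per-cell two-probe FISH table.

    coordinated_cis/trans place the second probe on the same/opposite homolog
    as the first before noise; independent and imprinted draw homologs
    independently (cis expectation 0.5).  ``detection_rate`` governs
    zero-signal probes, ``miscall_rate`` flips a probe's homolog, and
    ``biallelic_rate`` makes a probe show two signals.
    """
    if mode not in FISH_MODES:
        raise ValueError(f"mode must be one of {sorted(FISH_MODES)}")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    for r in (detection_rate, miscall_rate, biallelic_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = child_rng(seed, 400)
    pa, pb = probes
    cells: list[FishCellRecord] = []
    n_true_cis = 0
    for i in range(n_cells):
        h1 = "A" if rng.random() < 0.5 else "B"
        if mode == "coordinated_cis":
            h2 = h1
        elif mode == "coordinated_trans":
            h2 = "B" if h1 == "A" else "A"
        else:
            h2 = "A" if rng.random() < 0.5 else "B"
        n_true_cis += h1 == h2
        obs = {}
        homs = {}
        for probe, h in ((pa, h1), (pb, h2)):
            if rng.random() < biallelic_rate:
                obs[probe] = 2
                homs[probe] = None
                continue
            if rng.random() >= detection_rate:
                obs[probe] = 0
                homs[probe] = None
                continue
            if rng.random() < miscall_rate:
                h = "B" if h == "A" else "A"
            obs[probe] = 1
            homs[probe] = h
        if obs[pa] == 1 and obs[pb] == 1:
            config = "same_homolog" if homs[pa] == homs[pb] else "opposite_homolog"
        else:
            config = "unresolved"
        cells.append(FishCellRecord(f"cell{i + 1}", obs, config))
    truth = {"mode": mode, "true_cis_fraction": n_true_cis / n_cells, "seed": seed}
    return cells, truth


RETISH_MODES = {"async_cis", "async_trans", "synchronous"}


def simulate_retish_table(
    mode: str,
    n_cells: int,
    seed: int = 0,
    probes: tuple[str, str] = ("focal", "control"),
) -> tuple[list[ReTiSHRecord], dict]:
    """Per-cell ReTiSH records at the 5 h and 14 h BrdU time points.

    The 14 h pulse labels both homologs at every locus; centromeres label both
    homologs at both time points.  In the asynchronous modes each locus shows
    a single 5 h (late-S) signal: on the same homolog for both loci
    (async_cis) or on opposite homologs (async_trans).  synchronous shows the
    5 h signal on both homologs.
    """
    if mode not in RETISH_MODES:
        raise ValueError(f"mode must be one of {sorted(RETISH_MODES)}")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = child_rng(seed, 500)
    pa, pb = probes
    both = frozenset({"A", "B"})
    records: list[ReTiSHRecord] = []
    for i in range(n_cells):
        late = "A" if rng.random() < 0.5 else "B"
        other = "B" if late == "A" else "A"
        if mode == "async_cis":
            sig5 = {pa: frozenset({late}), pb: frozenset({late})}
        elif mode == "async_trans":
            sig5 = {pa: frozenset({late}), pb: frozenset({other})}
        else:
            sig5 = {pa: both, pb: both}
        cell = f"cell{i + 1}"
        records.append(ReTiSHRecord(cell, "5h", sig5, both))
        records.append(ReTiSHRecord(cell, "14h", {pa: both, pb: both}, both))
    return records, {"mode": mode, "seed": seed}


# --------------------------------------------------------------------------
# BrdU metaphase images


@dataclass
class BrdUImage:
    dapi: np.ndarray
    brdu: np.ndarray
    centromere: np.ndarray
    masks: dict[str, np.ndarray]  # truth masks keyed "6A"/"6B"
    true_ratio: float
    seed: int


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], ry: float, rx: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / ry) ** 2 + ((cc - center[1]) / rx) ** 2 <= 1.0


def simulate_brdu_image(
    ratio_6b_over_6a: float,
    shape: tuple[int, int] = (128, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
    dapi_level: float = 100.0,
    brdu_level_6a: float = 50.0,
    centromere_level: float = 200.0,
    body_semiaxes: tuple[float, float] = (48.0, 14.0),
    centromere_radii: tuple[float, float] = (7.0, 4.0),
) -> BrdUImage:
    """Two-homolog metaphase image triplet with a planted BrdU ratio.

    Two elongated chromosome bodies (axis-aligned ellipses of equal area)
    carry uniform DAPI; the 6B body's BrdU density is ``ratio`` times 6A's.
    The centromere channel has one blob per body, strictly larger on 6A.
    Which side 6A occupies is randomized per seed.  Gaussian noise of
    ``noise_sd`` is added to every channel and clipped at zero.
    """
    if ratio_6b_over_6a <= 0:
        raise ValueError("ratio must be positive")
    if min(shape) < 64:
        raise ValueError("grids must be at least 64x64")
    ry, rx = body_semiaxes
    h, w = shape
    centers = [(h / 2, w * 0.28), (h / 2, w * 0.72)]
    if centers[0][1] + rx >= centers[1][1] - rx:
        raise ValueError("chromosome bodies would overlap")
    rng = child_rng(seed, 600)
    a_side = int(rng.integers(0, 2))
    mask_a = _ellipse_mask(shape, centers[a_side], ry, rx)
    mask_b = _ellipse_mask(shape, centers[1 - a_side], ry, rx)
    dapi = np.where(mask_a | mask_b, dapi_level, 0.0)
    brdu = np.zeros(shape)
    brdu[mask_a] = brdu_level_6a
    brdu[mask_b] = brdu_level_6a * ratio_6b_over_6a
    cen = np.zeros(shape)
    r_a, r_b = centromere_radii
    if r_a <= r_b:
        raise ValueError("6A centromere must be strictly larger")
    cen[_ellipse_mask(shape, centers[a_side], r_a, r_a)] = centromere_level
    cen[_ellipse_mask(shape, centers[1 - a_side], r_b, r_b)] = centromere_level
    if noise_sd > 0:
        dapi = np.clip(dapi + rng.normal(0, noise_sd, shape), 0, None)
        brdu = np.clip(brdu + rng.normal(0, noise_sd, shape), 0, None)
        cen = np.clip(cen + rng.normal(0, noise_sd, shape), 0, None)
    return BrdUImage(
        dapi=dapi,
        brdu=brdu,
        centromere=cen,
        masks={"6A": mask_a, "6B": mask_b},
        true_ratio=float(ratio_6b_over_6a),
        seed=seed,
    )


# --------------------------------------------------------------------------
# manifest


def write_manifest(path: str | Path, config: SimulationConfig, extra: dict | None = None) -> None:
    """Record seeds and parameters sufficient to regenerate every output."""
    payload = {
        "master_seed": config.master_seed,
        "genome": config.genome,
        "l1_density": {c: config.chrom_l1_density(c) for c in config.genome},
        "domains": [
            {
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "strand": d.interval.strand,
                "depth": d.depth,
                "l1_target": d.l1_target,
                "name": d.name,
            }
            for d in config.domains
        ],
        "noise_model": config.noise_model,
        "background_rate": config.background_rate,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
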