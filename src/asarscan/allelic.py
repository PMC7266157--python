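"""Allelic-expression state calling and homolog assignment.

RNA allele counts at DNA-heterozygous SNPs are classified per SNP as
monoallelic / biallelic / indeterminate by a major-allele-fraction threshold,
the expressed homolog is resolved against mono-chromosomal hybrid genotypes
(each hybrid carries one of the two homologs, so its genotype phases every
informative SNP), and per-locus calls require agreement across SNPs.
Nuclear retention is summarized as a pseudocount-regularized
nuclear/cytoplasmic fold ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "AlleleCountRecord",
    "SnpAllelicState",
    "AllelicCall",
    "call_snp_allelic",
    "assign_expressed_homolog",
    "locus_allelic_call",
    "nuclear_enrichment",
    "read_allele_counts",
    "read_hybrid_table",
]

DEFAULT_MIN_DEPTH = 20
DEFAULT_MONO_THRESHOLD = 0.95


@dataclass(frozen=True)
class AlleleCountRecord:
    snp_id: str
    position: GenomicInterval  # length-1 interval
    ref_base: str
    alt_base: str
    dna_genotype: str  # het | hom_ref | hom_alt
    rna_ref_count: int
    rna_alt_count: int

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        if self.rna_ref_count < 0 or self.rna_alt_count < 0:
            raise ValueError("counts must be non-negative")
        if self.position.length != 1:
            raise ValueError("SNP position must be a length-1 interval")

    @property
    def depth(self) -> int:
        return self.rna_ref_count + self.rna_alt_count


@dataclass(frozen=True)
class SnpAllelicState:
    snp_id: str
    state: str  # monoallelic | biallelic | indeterminate
    major_fraction: float
    major_allele: str | None
    expressed_homolog: str = "unknown"  # A | B | unknown


@dataclass(frozen=True)
class AllelicCall:
    locus: str
    n_informative_snps: int
    major_allele_fraction: float
    state: str  # monoallelic | biallelic | indeterminate
    expressed_homolog: str  # A | B | unknown


def call_snp_allelic(
    record: AlleleCountRecord,
    min_depth: int = DEFAULT_MIN_DEPTH,
    mono_threshold: float = DEFAULT_MONO_THRESHOLD,
) -> SnpAllelicState:
    """Classify one DNA-heterozygous SNP from its RNA allele counts.

    Depth below ``min_depth`` is indeterminate; a major-allele fraction at or
    above ``mono_threshold`` (boundary inclusive) is monoallelic, anything
    between 0.5 and the threshold is biallelic.
    """
    if record.dna_genotype != "het":
        raise ValueError(
            f"SNP {record.snp_id} is {record.dna_genotype}, not heterozygous"
        )
    depth = record.depth
    if depth < min_depth:
        return SnpAllelicState(record.snp_id, "indeterminate", float("nan"), None)
    if record.rna_ref_count >= record.rna_alt_count:
        major, frac = record.ref_base, record.rna_ref_count / depth
    else:
        major, frac = record.alt_base, record.rna_alt_count / depth
    state = "monoallelic" if frac >= mono_threshold else "biallelic"
    return SnpAllelicState(record.snp_id, state, frac, major)


def assign_expressed_homolog(
    snp_state: SnpAllelicState,
    hybrids: Mapping[str, tuple[str, str]],
) -> str:
    """Map a monoallelic SNP's major allele onto homolog A or B.

    ``hybrids`` maps snp_id to the (homolog-A allele, homolog-B allele) pair
    read from the two mono-chromosomal hybrid genotypes.  The expressed major
    allele matching exactly one homolog assigns it; matching both, neither or
    a missing table entry yields "unknown".
    """
    if snp_state.major_allele is None:
        return "unknown"
    pair = hybrids.get(snp_state.snp_id)
    if pair is None:
        return "unknown"
    a_allele, b_allele = pair
    hits = [h for h, allele in (("A", a_allele), ("B", b_allele))
            if allele == snp_state.major_allele]
    return hits[0] if len(hits) == 1 else "unknown"


def locus_allelic_call(
    snp_states: Sequence[SnpAllelicState],
    min_snps: int = 1,
    locus: str = "",
) -> AllelicCall:
    """Aggregate per-SNP states into one locus call.

    Monoallelic requires every informative SNP monoallelic with agreeing
    homolog assignments (unknowns do not conflict); any biallelic SNP makes
    the locus biallelic; conflicting homologs make it indeterminate.
    """
    informative = [s for s in snp_states if s.state != "indeterminate"]
    if len(informative) < max(1, min_snps):
        return AllelicCall(locus, len(informative), float("nan"), "indeterminate", "unknown")
    mean_frac = sum(s.major_fraction for s in informative) / len(informative)
    if any(s.state == "biallelic" for s in informative):
        return AllelicCall(locus, len(informative), mean_frac, "biallelic", "unknown")
    homologs = {s.expressed_homolog for s in informative} - {"unknown"}
    if len(homologs) > 1:
        return AllelicCall(locus, len(informative), mean_frac, "indeterminate", "unknown")
    homolog = homologs.pop() if homologs else "unknown"
    return AllelicCall(locus, len(informative), mean_frac, "monoallelic", homolog)


def nuclear_enrichment(
    nuclear_level: float, cytoplasmic_level: float, pseudocount: float = 0.0
) -> float:
    """Nuclear/cytoplasmic fold ratio on a common normalized scale.

    Both levels zero means the locus is not expressed; that is reported as
    NaN rather than a ratio.  A pseudocount (smallest positive observable
    unit of the scale) regularizes zero denominators.
    """
    if nuclear_level < 0 or cytoplasmic_level < 0:
        raise ValueError("expression levels must be non-negative")
    if nuclear_level == 0 and cytoplasmic_level == 0:
        return float("nan")
    if cytoplasmic_level + pseudocount == 0:
        return float("inf")
    return (nuclear_level + pseudocount) / (cytoplasmic_level + pseudocount)


# --------------------------------------------------------------------------
# TSV adapters

ALLELE_COUNT_COLUMNS = [
    "snp_id", "chrom", "pos", "ref", "alt", "dna_gt", "rna_ref", "rna_alt",
]


def read_allele_counts(path) -> list[AlleleCountRecord]:
    """Read allele counts from TSV (columns: snp_id, chrom, pos, ref, alt,
    dna_gt, rna_ref, rna_alt; pos is 0-based)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ALLELE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-count table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AlleleCountRecord(
                snp_id=str(row.snp_id),
                position=GenomicInterval(str(row.chrom), int(row.pos), int(row.pos) + 1),
                ref_base=str(row.ref),
                alt_base=str(row.alt),
                dna_genotype=str(row.dna_gt),
                rna_ref_count=int(row.rna_ref),
                rna_alt_count=int(row.rna_alt),
            )
        )
    return records


def read_hybrid_table(path) -> dict[str, tuple[str, str]]:
    """Read the mono-chromosomal hybrid genotypes from TSV (columns: snp_id,
    homolog_a_allele, homolog_b_allele)."""
    df = pd.read_csv(path, sep="\t")
    need = {"snp_id", "homolog_a_allele", "homolog_b_allele"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"hybrid table missing columns: {sorted(missing)}")
    return {
        str(r.snp_id): (str(r.homolog_a_allele), str(r.homolog_b_allele))
        for r in df.itertuples(index=False)
    }
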