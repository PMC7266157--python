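"""Contiguous transcribed-domain (vlinc) calling from coverage.

vlincRNAs are operationally defined as >50 kb of contiguously expressed,
nonspliced sequence not associated with protein-coding genes.  The caller
finds maximal runs of positions at or above a depth threshold, bridges short
sub-threshold gaps, and keeps runs at least ``min_len`` long; a separate
filter removes domains overlapping protein-coding gene bodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CoverageTrack
from .intervals import FeatureSet, GenomicInterval, merge_by_chrom, overlap_length

__all__ = [
    "TranscribedDomain",
    "call_transcribed_domains",
    "filter_protein_coding",
    "resolve_min_cov",
]

DEFAULT_MIN_LEN = 50_000
MIN_COV_MEDIAN_FRACTION = 0.25
MIN_COV_FLOOR = 2.0


@dataclass(frozen=True)
class TranscribedDomain:
    interval: GenomicInterval
    mean_depth: float
    n_gaps_bridged: int = 0

    @property
    def length(self) -> int:
        return self.interval.length


def resolve_min_cov(track: CoverageTrack, min_cov: float | None) -> float:
    """Default depth threshold: a fraction of the track's nonzero median with
    an absolute floor, so the caller adapts to sequencing depth."""
    if min_cov is not None:
        if min_cov <= 0:
            raise ValueError("min_cov must be positive")
        return float(min_cov)
    return max(MIN_COV_FLOOR, MIN_COV_MEDIAN_FRACTION * track.nonzero_median())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def call_transcribed_domains(
    track: CoverageTrack,
    min_cov: float | None = None,
    max_gap: int = 0,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[TranscribedDomain]:
    """Call maximal contiguously-covered domains.

    Positions with depth >= ``min_cov`` seed runs; consecutive runs separated
    by <= ``max_gap`` sub-threshold bases are bridged into one domain.  Runs
    shorter than ``min_len`` after bridging are dropped.  Bridged bases count
    toward domain length but not toward the mean-depth numerator, so
    ``mean_depth`` reflects observed signal over the genomic span.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    threshold = resolve_min_cov(track, min_cov)
    strand = track.strand
    domains: list[TranscribedDomain] = []
    for chrom in sorted(track.chroms()):
        vec = track.depth(chrom)
        mask = vec >= threshold
        runs = _runs(mask)
        if not runs:
            continue
        # bridge gaps <= max_gap
        bridged: list[list[int]] = [[runs[0][0], runs[0][1], 0]]
        for s, e in runs[1:]:
            last = bridged[-1]
            if s - last[1] <= max_gap:
                last[1] = e
                last[2] += 1
            else:
                bridged.append([s, e, 0])
        for s, e, n_gaps in bridged:
            if e - s < min_len:
                continue
            span = vec[s:e]
            signal = span[span >= threshold].sum()
            domains.append(
                TranscribedDomain(
                    GenomicInterval(chrom, s, e, strand),
                    mean_depth=float(signal / (e - s)),
                    n_gaps_bridged=n_gaps,
                )
            )
    return domains


def filter_protein_coding(
    domains: list[TranscribedDomain],
    genes: FeatureSet,
    max_cds_overlap_bases: int = 0,
) -> list[TranscribedDomain]:
    """Drop domains overlapping protein-coding gene bodies by more than
    ``max_cds_overlap_bases`` (default: any overlap disqualifies).

    Overlap is computed against the merged union of gene bodies on either
    strand: vlincRNAs are intergenic by definition, so the conservative
    gene-body rule (rather than exon-only) is applied.
    """
    coding = merge_by_chrom(
        f.interval
        for f in genes
        if f.kind == "gene" and f.family == "protein_coding"
    )
    kept = []
    for d in domains:
        bodies = coding.get(d.interval.chrom, [])
        if overlap_length(d.interval, bodies) <= max_cds_overlap_bases:
            kept.append(d)
    return kept
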