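"""Genomic interval algebra.

All coordinates are 0-based half-open throughout the package; conversion to
and from 1-based closed conventions (GFF3/GTF, RepeatMasker) happens only in
:mod:`asarscan.io`.  Strand is ``"+"``, ``"-"`` or ``"."`` (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

__all__ = [
    "GenomicInterval",
    "Feature",
    "FeatureSet",
    "merge_intervals",
    "merge_by_chrom",
    "subtract_intervals",
    "overlap_length",
    "total_length",
]

_STRANDS = {"+", "-", "."}
FEATURE_KINDS = {"gene", "exon", "intron", "repeat", "domain"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Feature:
    """An annotated interval: gene, exon, intron, repeat or transcribed domain.

    ``family`` carries the RepeatMasker class/family token for repeats (e.g.
    ``"LINE/L1"``) or the biotype for genes (e.g. ``"protein_coding"``).
    """

    interval: GenomicInterval
    kind: str
    family: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        if self.kind == "repeat" and not self.family:
            raise ValueError("repeat features require a non-empty family")


@dataclass
class FeatureSet:
    """Ordered collection of features with optional chromosome sizes."""

    features: list[Feature] = field(default_factory=list)
    genome: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genome:
            for f in self.features:
                size = self.genome.get(f.interval.chrom)
                if size is not None and f.interval.end > size:
                    raise ValueError(
                        f"feature {f.name or f.interval} exceeds length of "
                        f"{f.interval.chrom} ({size})"
                    )

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def subset(
        self,
        kind: str | None = None,
        family: str | Callable[[str], bool] | None = None,
        chrom: str | None = None,
    ) -> "FeatureSet":
        """Filter by kind, family (exact string or predicate) and chromosome."""
        out = []
        for f in self.features:
            if kind is not None and f.kind != kind:
                continue
            if chrom is not None and f.interval.chrom != chrom:
                continue
            if family is not None:
                ok = family(f.family) if callable(family) else f.family == family
                if not ok:
                    continue
            out.append(f)
        return FeatureSet(out, dict(self.genome))

    def intervals(self) -> list[GenomicInterval]:
        return [f.interval for f in self.features]

    def chroms(self) -> list[str]:
        seen = dict.fromkeys(f.interval.chrom for f in self.features)
        return list(seen)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and abutting intervals on a single chromosome.

    Returns a sorted, pairwise-disjoint list covering exactly the union of the
    input bases.  Strand is dropped (merged intervals are unstranded).
    """
    ivs = list(intervals)
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(f"merge_intervals requires one chromosome, got {sorted(chroms)}")
    chrom = chroms.pop()
    ivs.sort(key=lambda iv: (iv.start, iv.end))
    merged: list[list[int]] = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last[1]:  # overlap or abutting
            last[1] = max(last[1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [GenomicInterval(chrom, s, e) for s, e in merged]


def merge_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    """Merge intervals chromosome by chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return {c: merge_intervals(ivs) for c, ivs in sorted(by_chrom.items())}


def subtract_intervals(
    minuend: Iterable[GenomicInterval], subtrahend: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``minuend`` not covered by ``subtrahend`` (any chromosomes)."""
    sub = merge_by_chrom(subtrahend)
    out: list[GenomicInterval] = []
    for chrom, ivs in merge_by_chrom(minuend).items():
        cuts = sub.get(chrom, [])
        for iv in ivs:
            pos = iv.start
            for c in cuts:
                if c.end <= pos or c.start >= iv.end:
                    continue
                if c.start > pos:
                    out.append(GenomicInterval(chrom, pos, c.start))
                pos = max(pos, c.end)
                if pos >= iv.end:
                    break
            if pos < iv.end:
                out.append(GenomicInterval(chrom, pos, iv.end))
    return out


def overlap_length(
    query: GenomicInterval, subject: Iterable[GenomicInterval]
) -> int:
    """Number of bases of ``query`` covered by the union of ``subject``.

    Subject intervals on other chromosomes contribute nothing.  Overlapping
    subject intervals are never double counted.
    """
    same = [iv for iv in subject if iv.chrom == query.chrom]
    if not same:
        return 0
    return sum(query.intersection_length(iv) for iv in merge_intervals(same))


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total union length across chromosomes."""
    return sum(
        iv.length for ivs in merge_by_chrom(intervals).values() for iv in ivs
    )
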