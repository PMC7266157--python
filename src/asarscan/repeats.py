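"""L1 repeat composition and the intron-resampling beta null.

A candidate domain's LINE-1 content is compared to the genomic background by
repeatedly assembling random intronic sequence of the same total length,
measuring the L1-covered fraction of each replicate, fitting a beta
distribution to the replicate fractions by the method of moments, and reading
an upper-tail p-value for the observed fraction off the fitted beta (an
empirical rank p-value is always computed alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .intervals import (
    Feature,
    FeatureSet,
    GenomicInterval,
    merge_by_chrom,
    merge_intervals,
    overlap_length,
    subtract_intervals,
)

__all__ = [
    "RepeatComposition",
    "ResamplingNull",
    "BetaFitError",
    "is_l1",
    "l1_fraction",
    "build_intron_set",
    "sample_intron_null",
    "fit_beta_mom",
    "l1_enrichment_pvalue",
]


def is_l1(family: str) -> bool:
    """L1 membership for a RepeatMasker class/family token.

    Accepts ``LINE/L1`` style tokens (class LINE, family starting "L1") and
    bare ``L1``/``L1PA3``-style labels.
    """
    if "/" in family:
        cls, _, fam = family.partition("/")
        return cls == "LINE" and fam.startswith("L1")
    return family.startswith("L1")


@dataclass(frozen=True)
class RepeatComposition:
    interval: GenomicInterval
    l1_fraction: float
    antisense_l1_fraction: float
    per_family_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.l1_fraction, self.antisense_l1_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {v}")
        if self.antisense_l1_fraction > self.l1_fraction + 1e-12:
            raise ValueError("antisense L1 fraction cannot exceed total L1 fraction")


@dataclass
class ResamplingNull:
    replicate_fractions: np.ndarray
    target_length: int
    seed: int
    alpha: float | None = None
    beta: float | None = None

    @property
    def n_reps(self) -> int:
        return int(len(self.replicate_fractions))

    @property
    def fit_ok(self) -> bool:
        return self.alpha is not None and self.beta is not None


class BetaFitError(ValueError):
    """Replicate fractions are degenerate; no beta fit is available."""


def _opposite(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, ".")


def l1_fraction(
    interval: GenomicInterval,
    repeats: FeatureSet,
    transcription_strand: str | None = None,
    l1_predicate: Callable[[str], bool] = is_l1,
) -> RepeatComposition:
    """L1-covered fraction of an interval, on merged repeat unions.

    When ``transcription_strand`` is given, the antisense fraction counts only
    L1 copies on the opposite strand (antisense L1 content is the ASAR RNA
    hallmark); otherwise it is 0.
    """
    feats = [
        f
        for f in repeats
        if f.kind == "repeat" and f.interval.chrom == interval.chrom
    ]
    l1_feats = [f for f in feats if l1_predicate(f.family)]
    l1_bases = overlap_length(interval, [f.interval for f in l1_feats])
    if transcription_strand in {"+", "-"}:
        anti = [
            f.interval
            for f in l1_feats
            if f.interval.strand == _opposite(transcription_strand)
        ]
        anti_bases = overlap_length(interval, anti)
    else:
        anti_bases = 0
    per_family: dict[str, float] = {}
    by_family: dict[str, list[GenomicInterval]] = {}
    for f in feats:
        by_family.setdefault(f.family, []).append(f.interval)
    for fam, ivs in sorted(by_family.items()):
        per_family[fam] = overlap_length(interval, ivs) / interval.length
    return RepeatComposition(
        interval=interval,
        l1_fraction=l1_bases / interval.length,
        antisense_l1_fraction=anti_bases / interval.length,
        per_family_fractions=per_family,
    )


def build_intron_set(genes: FeatureSet) -> list[GenomicInterval]:
    """Intronic intervals: per-gene gaps between consecutive exons, merged
    across genes, with any exon-overlapping bases subtracted.

    Genes with fewer than two exons contribute nothing.  The result is the
    exon-free interior of gene bodies, suitable as the sampling universe for
    the resampling null.
    """
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    all_exons: list[GenomicInterval] = []
    for f in genes:
        if f.kind == "exon":
            exons_by_gene.setdefault(f.name, []).append(f.interval)
            all_exons.append(f.interval)
    introns: list[GenomicInterval] = []
    for _gene, exons in sorted(exons_by_gene.items()):
        by_chrom = merge_by_chrom(exons)
        for chrom, merged in by_chrom.items():
            for left, right in zip(merged, merged[1:]):
                introns.append(GenomicInterval(chrom, left.end, right.start))
    if not introns:
        return []
    return subtract_intervals(introns, all_exons)


def _l1_prefix_index(
    introns: Sequence[GenomicInterval],
    repeats: FeatureSet,
    l1_predicate: Callable[[str], bool],
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per intron: L1 segment starts/ends (intron-relative) and cumulative
    covered length before each segment, enabling O(log k) window queries."""
    l1_by_chrom = merge_by_chrom(
        f.interval
        for f in repeats
        if f.kind == "repeat" and l1_predicate(f.family)
    )
    index = []
    for intron in introns:
        segs = []
        for iv in l1_by_chrom.get(intron.chrom, []):
            s = max(iv.start, intron.start)
            e = min(iv.end, intron.end)
            if s < e:
                segs.append((s - intron.start, e - intron.start))
        starts = np.array([s for s, _ in segs], dtype=float)
        ends = np.array([e for _, e in segs], dtype=float)
        cum = np.concatenate(([0.0], np.cumsum(ends - starts)))
        index.append((starts, ends, cum))
    return index


def _covered_in_window(
    idx: tuple[np.ndarray, np.ndarray, np.ndarray], lo: float, hi: float
) -> float:
    """L1-covered bases within intron-relative window [lo, hi)."""
    starts, ends, cum = idx
    if starts.size == 0 or hi <= lo:
        return 0.0

    def covered_before(x: float) -> float:
        i = int(np.searchsorted(ends, x, side="left"))
        base = cum[i]
        if i < starts.size and starts[i] < x:
            base += x - starts[i]
        return float(base)

    return covered_before(hi) - covered_before(lo)


def sample_intron_null(
    introns: Sequence[GenomicInterval],
    repeats: FeatureSet,
    L: int,
    n_reps: int = 10_000,
    seed: int = 0,
    l1_predicate: Callable[[str], bool] = is_l1,
) -> ResamplingNull:
    """Build the intron-resampling null for an observed span of length ``L``.

    Each replicate draws introns uniformly with replacement, concatenating
    whole introns until the cumulative length reaches ``L``; the final intron
    is trimmed to the exact remaining length from a uniformly chosen in-intron
    start.  The replicate statistic is the L1-covered fraction of the
    assembled sequence.  Introns are sorted canonically before sampling so the
    draw depends only on the seed, not on input order.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    ivs = sorted(merge_intervals_multichrom(introns), key=lambda iv: (iv.chrom, iv.start))
    lengths = np.array([iv.length for iv in ivs], dtype=float)
    if lengths.sum() < L:
        raise ValueError(
            f"total intronic length {int(lengths.sum())} < target length {L}"
        )
    index = _l1_prefix_index(ivs, repeats, l1_predicate)
    full_l1 = np.array([idx[2][-1] for idx in index])
    rng = np.random.default_rng(seed)
    n = len(ivs)
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        covered = 0.0
        acc = 0.0
        while True:
            i = int(rng.integers(n))
            if acc + lengths[i] < L:
                acc += lengths[i]
                covered += full_l1[i]
            else:
                rem = L - acc
                lo = float(rng.uniform(0.0, lengths[i] - rem))
                covered += _covered_in_window(index[i], lo, lo + rem)
                break
        fractions[rep] = covered / L
    null = ResamplingNull(fractions, target_length=L, seed=seed)
    try:
        null.alpha, null.beta = fit_beta_mom(fractions)
    except BetaFitError:
        null.alpha = null.beta = None
    return null


def merge_intervals_multichrom(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for _chrom, ivs in merge_by_chrom(intervals).items():
        out.extend(ivs)
    return out


def fit_beta_mom(fractions: Sequence[float]) -> tuple[float, float]:
    """Method-of-moments beta fit.

    With sample mean ``m`` and variance ``v``: ``c = m(1-m)/v - 1``,
    ``alpha = m*c``, ``beta = (1-m)*c``.  Requires 0 < v < m(1-m).
    """
    x = np.asarray(fractions, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise BetaFitError("need at least two distinct values")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if not 0.0 < v < m * (1.0 - m):
        raise BetaFitError(f"variance {v} outside (0, m(1-m)) for mean {m}")
    c = m * (1.0 - m) / v - 1.0
    return m * c, (1.0 - m) * c


def l1_enrichment_pvalue(
    null: ResamplingNull, observed: float, method: str = "beta_tail"
) -> float:
    """Upper-tail p-value for an observed L1 fraction against the null.

    ``beta_tail`` evaluates the fitted beta survival function at the observed
    value; ``empirical`` is the rank statistic (r+1)/(n+1) with r the number
    of replicates at or above the observed value.  Both lie in (0, 1].
    """
    if not 0.0 <= observed <= 1.0:
        raise ValueError("observed fraction must be in [0, 1]")
    if method == "empirical":
        r = int((null.replicate_fractions >= observed).sum())
        return (r + 1) / (null.n_reps + 1)
    if method == "beta_tail":
        if not null.fit_ok:
            raise BetaFitError(
                "beta fit unavailable (degenerate replicates); use method='empirical'"
            )
        p = float(stats.beta.sf(observed, null.alpha, null.beta))
        return min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    raise ValueError(f"unknown method {method!r}")
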