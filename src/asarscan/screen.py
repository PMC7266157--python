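"""The ASAR-candidate screen: orchestration of all stages.

A candidate locus must be a long (>50 kb) contiguously transcribed domain
not associated with protein-coding genes, nuclear-retained, monoallelically
expressed, and significantly L1-enriched against the intron-resampling
null.  Each criterion becomes a named boolean flag traceable to a numeric
column and threshold in the report; candidacy is the conjunction of flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .allelic import (
    AlleleCountRecord,
    AllelicCall,
    assign_expressed_homolog,
    call_snp_allelic,
    locus_allelic_call,
    nuclear_enrichment,
)
from .coverage import CoverageTrack
from .domains import (
    DEFAULT_MIN_LEN,
    TranscribedDomain,
    call_transcribed_domains,
    filter_protein_coding,
)
from .intervals import FeatureSet, GenomicInterval
from .repeats import (
    RepeatComposition,
    ResamplingNull,
    build_intron_set,
    l1_enrichment_pvalue,
    l1_fraction,
    sample_intron_null,
)

__all__ = ["ScreenThresholds", "CandidateLocus", "screen_candidates", "candidates_to_frame"]


@dataclass(frozen=True)
class ScreenThresholds:
    min_len: int = DEFAULT_MIN_LEN
    min_cov: float | None = None
    max_gap: int = 0
    max_coding_overlap: int = 0
    min_nuclear_fold: float = 5.0
    max_l1_pvalue: float = 0.05
    min_depth: int = 20
    mono_threshold: float = 0.95
    n_reps: int = 10_000


@dataclass
class CandidateLocus:
    domain: TranscribedDomain
    composition: RepeatComposition
    nuclear_fold: float
    allelic: AllelicCall
    l1_p_beta: float
    l1_p_empirical: float
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def asar_candidate(self) -> bool:
        return all(self.flags.values())


def _counts_in(interval: GenomicInterval, counts: list[AlleleCountRecord]) -> list[AlleleCountRecord]:
    return [c for c in counts if interval.contains(c.position)]


def screen_candidates(
    track: CoverageTrack,
    genes: FeatureSet,
    repeats: FeatureSet,
    allele_counts: list[AlleleCountRecord] | None = None,
    hybrids: dict[str, tuple[str, str]] | None = None,
    nuclear_track: CoverageTrack | None = None,
    cytoplasmic_track: CoverageTrack | None = None,
    thresholds: ScreenThresholds = ScreenThresholds(),
    seed: int = 0,
) -> list[CandidateLocus]:
    """Run the full screen over one coverage track.

    Stages: call transcribed domains, drop protein-coding-associated ones,
    annotate L1 composition and intron-null enrichment, nuclear fold ratio
    (from paired nuclear/cytoplasmic tracks when given, else from the main
    track treated as nuclear with zero cytoplasmic signal unavailable ->
    flag passes only when tracks are supplied), and the locus allelic call.
    One resampling null is shared by all candidates of equal span length.
    """
    t = thresholds
    domains = call_transcribed_domains(
        track, min_cov=t.min_cov, max_gap=t.max_gap, min_len=t.min_len
    )
    domains = filter_protein_coding(domains, genes, t.max_coding_overlap)
    if not domains:
        return []
    introns = build_intron_set(genes)
    null_cache: dict[int, ResamplingNull] = {}
    out: list[CandidateLocus] = []
    for dom in domains:
        comp = l1_fraction(
            dom.interval,
            repeats,
            transcription_strand=dom.interval.strand if dom.interval.strand in "+-" else None,
        )
        L = dom.interval.length
        if L not in null_cache:
            null_cache[L] = sample_intron_null(
                introns, repeats, L, n_reps=t.n_reps, seed=seed
            )
        null = null_cache[L]
        p_emp = l1_enrichment_pvalue(null, comp.l1_fraction, method="empirical")
        p_beta = (
            l1_enrichment_pvalue(null, comp.l1_fraction, method="beta_tail")
            if null.fit_ok
            else p_emp
        )
        if nuclear_track is not None and cytoplasmic_track is not None:
            fold = nuclear_enrichment(
                nuclear_track.mean_depth(dom.interval),
                cytoplasmic_track.mean_depth(dom.interval),
                pseudocount=1.0 / dom.interval.length,
            )
        else:
            fold = float("nan")
        counts = _counts_in(dom.interval, allele_counts or [])
        states = []
        for rec in counts:
            state = call_snp_allelic(rec, t.min_depth, t.mono_threshold)
            if hybrids and state.state == "monoallelic":
                state = type(state)(
                    state.snp_id,
                    state.state,
                    state.major_fraction,
                    state.major_allele,
                    assign_expressed_homolog(state, hybrids),
                )
            states.append(state)
        call = locus_allelic_call(states, locus=f"{dom.interval.chrom}:{dom.interval.start}-{dom.interval.end}")
        flags = {
            "length_ok": dom.interval.length >= t.min_len,
            "noncoding_ok": True,  # survivors of filter_protein_coding
            "nuclear_ok": bool(fold >= t.min_nuclear_fold) if fold == fold else False,
            "monoallelic_ok": call.state == "monoallelic",
            "l1_enriched_ok": p_beta < t.max_l1_pvalue,
        }
        out.append(CandidateLocus(dom, comp, fold, call, p_beta, p_emp, flags))
    return out


def candidates_to_frame(candidates: list[CandidateLocus]) -> pd.DataFrame:
    """Flatten candidates into the report table, ranked by candidacy then
    enrichment p-value."""
    rows = []
    for c in candidates:
        iv = c.domain.interval
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "length": iv.length,
                "mean_depth": c.domain.mean_depth,
                "l1_fraction": c.composition.l1_fraction,
                "antisense_l1_fraction": c.composition.antisense_l1_fraction,
                "l1_p_beta": c.l1_p_beta,
                "l1_p_empirical": c.l1_p_empirical,
                "nuclear_fold": c.nuclear_fold,
                "allelic_state": c.allelic.state,
                "expressed_homolog": c.allelic.expressed_homolog,
                "n_informative_snps": c.allelic.n_informative_snps,
                **c.flags,
                "asar_candidate": c.asar_candidate,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["asar_candidate", "l1_p_beta"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
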