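"""Cytogenetic scoring: RNA-FISH signal counts, cis/trans coordination, and
ReTiSH replication-asynchrony classification.

Coordination logic distinguishes random monoallelic expression from
imprinting: two loci both subject to programmed random monoallelic
expression are expressed from the same homolog in nearly all cells of a
non-clonal population (coordinated), whereas an imprinted locus paired with
a random one lands on the same homolog in only ~50% of cells.  The test is
an exact two-sided binomial test of the cis count against p = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

__all__ = [
    "FishCellRecord",
    "CoordinationResult",
    "ReTiSHRecord",
    "RetishCellCall",
    "summarize_fish_counts",
    "score_cis_trans",
    "classify_retish_cell",
    "aggregate_retish",
]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class FishCellRecord:
    """Per-cell RNA-FISH observation for one or two probes.

    ``signals`` maps probe name to its signal count (0, 1 or 2).
    ``configuration`` is defined only when both probes of a pair show exactly
    one signal: ``same_homolog``, ``opposite_homolog`` or ``unresolved``.
    """

    cell_id: str
    signals: Mapping[str, int] = field(default_factory=dict)
    configuration: str = "unresolved"

    def __post_init__(self) -> None:
        for probe, n in self.signals.items():
            if n not in (0, 1, 2):
                raise ValueError(f"probe {probe}: signal count must be 0, 1 or 2")
        if self.configuration not in {"same_homolog", "opposite_homolog", "unresolved"}:
            raise ValueError(f"bad configuration {self.configuration!r}")


@dataclass(frozen=True)
class CoordinationResult:
    n_cis: int
    n_trans: int
    p_value: float
    classification: str  # coordinated_cis | coordinated_trans | not_coordinated
    n_excluded_biallelic: int = 0

    @property
    def cis_fraction(self) -> float:
        return self.n_cis / (self.n_cis + self.n_trans)


def summarize_fish_counts(
    cells: Sequence[FishCellRecord], probe: str
) -> dict[int, float]:
    """Fractions of cells with 0 / 1 / 2 signals for one probe.

    The fraction with exactly one signal is the monoallelic-expression
    read-out quoted per cell line (e.g. single sites in >80% of cells).
    """
    if not cells:
        raise ValueError("no cells supplied")
    counts = {0: 0, 1: 0, 2: 0}
    for cell in cells:
        counts[cell.signals.get(probe, 0)] += 1
    n = len(cells)
    return {k: v / n for k, v in counts.items()}


def _binom_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial p at p0=0.5: sum of all outcome probabilities
    no larger than that of the observed count."""
    return float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)


def score_cis_trans(
    cells: Sequence[FishCellRecord],
    probe_pair: tuple[str, str],
    alpha: float = DEFAULT_ALPHA,
) -> CoordinationResult:
    """Exact binomial coordination test over doubly single-signal cells.

    Cells where either probe shows two signals (biallelic-appearing, a few
    percent in practice) are excluded from the test and tallied separately.
    """
    pa, pb = probe_pair
    n_cis = n_trans = n_biallelic = 0
    for cell in cells:
        sa, sb = cell.signals.get(pa, 0), cell.signals.get(pb, 0)
        if sa == 2 or sb == 2:
            n_biallelic += 1
            continue
        if sa == 1 and sb == 1 and cell.configuration != "unresolved":
            if cell.configuration == "same_homolog":
                n_cis += 1
            else:
                n_trans += 1
    n = n_cis + n_trans
    if n == 0:
        raise ValueError(
            "no informative cells (need both probes single-signal with a "
            "resolved configuration)"
        )
    p = _binom_two_sided(n_cis, n)
    if p < alpha:
        classification = "coordinated_cis" if n_cis > n_trans else "coordinated_trans"
    else:
        classification = "not_coordinated"
    return CoordinationResult(n_cis, n_trans, p, classification, n_biallelic)


# --------------------------------------------------------------------------
# ReTiSH


@dataclass(frozen=True)
class ReTiSHRecord:
    """Hybridization pattern of one cell at one BrdU time point.

    ``probe_homologs`` maps locus probe to the set of homologs ("A"/"B")
    showing signal; ``centromere_homologs`` is the chromosome-6 centromere
    control, expected on both homologs at both time points.
    """

    cell_id: str
    timepoint: str  # "5h" | "14h"
    probe_homologs: Mapping[str, frozenset] = field(default_factory=dict)
    centromere_homologs: frozenset = frozenset({"A", "B"})

    def __post_init__(self) -> None:
        if self.timepoint not in {"5h", "14h"}:
            raise ValueError("timepoint must be '5h' or '14h'")


@dataclass(frozen=True)
class RetishCellCall:
    cell_id: str
    probe: str
    status: str  # asynchronous | synchronous_late | synchronous_early | qc_fail
    late_homolog: str | None = None


def classify_retish_cell(
    record_5h: ReTiSHRecord, record_14h: ReTiSHRecord, probe: str
) -> RetishCellCall:
    """Classify replication asynchrony of one locus in one cell.

    The 14 h pulse spans all of S phase, so its signal must be on both
    homologs (and the late-replicating centromere must light up both homologs
    at both time points) — anything else is a QC failure.  The 5 h pulse
    covers only late S phase: signal on exactly one homolog marks that
    homolog as late-replicating (asynchronous); on both, synchronous-late;
    on neither, synchronous-early.
    """
    if record_5h.cell_id != record_14h.cell_id:
        raise ValueError("records are from different cells")
    both = frozenset({"A", "B"})
    if record_5h.centromere_homologs != both or record_14h.centromere_homologs != both:
        return RetishCellCall(record_5h.cell_id, probe, "qc_fail")
    if record_14h.probe_homologs.get(probe, frozenset()) != both:
        return RetishCellCall(record_5h.cell_id, probe, "qc_fail")
    sig5 = record_5h.probe_homologs.get(probe, frozenset())
    if len(sig5) == 1:
        (late,) = sig5
        return RetishCellCall(record_5h.cell_id, probe, "asynchronous", late)
    if sig5 == both:
        return RetishCellCall(record_5h.cell_id, probe, "synchronous_late")
    return RetishCellCall(record_5h.cell_id, probe, "synchronous_early")


def aggregate_retish(
    cells: Iterable[ReTiSHRecord], probe_a: str, probe_b: str
) -> dict:
    """Cis/trans coordination of asynchronous replication across two loci.

    Cells where both probes classify as asynchronous contribute: cis when the
    late alleles sit on the same homolog, trans otherwise.  Returns counts,
    fractions and the QC-failure tally.
    """
    by_cell: dict[str, dict[str, ReTiSHRecord]] = {}
    for rec in cells:
        by_cell.setdefault(rec.cell_id, {})[rec.timepoint] = rec
    n_cis = n_trans = n_qc_fail = n_uninformative = 0
    for cell_id, recs in sorted(by_cell.items()):
        if set(recs) != {"5h", "14h"}:
            n_qc_fail += 1
            continue
        calls = {
            p: classify_retish_cell(recs["5h"], recs["14h"], p)
            for p in (probe_a, probe_b)
        }
        if any(c.status == "qc_fail" for c in calls.values()):
            n_qc_fail += 1
            continue
        if all(c.status == "asynchronous" for c in calls.values()):
            if calls[probe_a].late_homolog == calls[probe_b].late_homolog:
                n_cis += 1
            else:
                n_trans += 1
        else:
            n_uninformative += 1
    n = n_cis + n_trans
    return {
        "n_cis": n_cis,
        "n_trans": n_trans,
        "cis_fraction": n_cis / n if n else float("nan"),
        "trans_fraction": n_trans / n if n else float("nan"),
        "n_qc_fail": n_qc_fail,
        "n_uninformative": n_uninformative,
    }
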