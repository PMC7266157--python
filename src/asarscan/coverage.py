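"""Dense per-base read-depth tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval

__all__ = ["CoverageTrack"]


@dataclass
class CoverageTrack:
    """Per-chromosome dense depth vectors, optionally strand-specific.

    ``data`` maps chromosome name to a non-negative float vector whose index
    is the 0-based genomic position.  ``strand`` is "+", "-" for a
    strand-specific track or "." for an unstranded one.
    """

    data: dict[str, np.ndarray] = field(default_factory=dict)
    strand: str = "."

    def __post_init__(self) -> None:
        for chrom, vec in self.data.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"depth vector for {chrom} must be 1-D")
            if (arr < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self.data[chrom] = arr

    def chroms(self) -> list[str]:
        return list(self.data)

    def depth(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def region(self, interval: GenomicInterval) -> np.ndarray:
        vec = self.data.get(interval.chrom)
        if vec is None:
            return np.zeros(interval.length)
        out = np.zeros(interval.length)
        hi = min(interval.end, len(vec))
        if hi > interval.start:
            out[: hi - interval.start] = vec[interval.start : hi]
        return out

    def mean_depth(self, interval: GenomicInterval) -> float:
        return float(self.region(interval).mean())

    def nonzero_median(self) -> float:
        """Median depth over positions with any signal; 0 for an empty track."""
        vals = [vec[vec > 0] for vec in self.data.values()]
        vals = [v for v in vals if v.size]
        if not vals:
            return 0.0
        return float(np.median(np.concatenate(vals)))

    def is_empty(self) -> bool:
        return all((vec == 0).all() for vec in self.data.values()) or not self.data
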