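"""BrdU replication-timing quantification from metaphase chromosome images.

Each metaphase cell contributes two chromosome-6 homologs distinguished by a
centromere-size polymorphism (larger centromere = 6A).  BrdU incorporation
per homolog is total fluorescence = mean pixel intensity x pixel area
(identically the pixel sum over the mask), and each cell is summarized by
the 6B/6A ratio.  Genotype groups of cells are compared with a tie-corrected
Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "ChromosomeMeasurement",
    "BrdUCellRatio",
    "GroupComparison",
    "segment_chromosomes",
    "identify_homologs",
    "measure_chromosome",
    "brdu_ratio",
    "measure_cell_image",
    "kruskal_wallis",
    "read_measurements",
]

DEFAULT_MIN_AREA = 50
DEFAULT_CENTROMERE_MARGIN = 0.10


@dataclass(frozen=True)
class ChromosomeMeasurement:
    cell_id: str
    homolog: str  # "6A" | "6B"
    pixel_area: int
    mean_brdu_intensity: float
    mean_dapi_intensity: float

    def __post_init__(self) -> None:
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if self.mean_brdu_intensity < 0 or self.mean_dapi_intensity < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def total_brdu(self) -> float:
        return self.mean_brdu_intensity * self.pixel_area


@dataclass(frozen=True)
class BrdUCellRatio:
    cell_id: str
    ratio: float  # total_brdu(6B) / total_brdu(6A)
    group: str = ""

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("ratio must be positive")


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    sizes: tuple[int, ...]
    h_statistic: float
    df: int
    p_value: float


# --------------------------------------------------------------------------
# image path


def segment_chromosomes(
    dapi_grid: np.ndarray, min_area: int = DEFAULT_MIN_AREA
) -> list[np.ndarray]:
    """Segment chromosome bodies from the DAPI channel.

    Global Otsu threshold, connected components, components below ``min_area``
    pixels discarded.  Masks are returned sorted by centroid (row, then
    column) so repeated runs label identically.
    """
    grid = np.asarray(dapi_grid, dtype=float)
    if grid.ndim != 2 or min(grid.shape) < 64:
        raise ValueError("DAPI grid must be 2-D and at least 64x64")
    if np.allclose(grid, grid.flat[0]):
        return []
    thresh = threshold_otsu(grid)
    labels = measure.label(grid > thresh)
    masks = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        masks.append((region.centroid, labels == region.label))
    masks.sort(key=lambda t: t[0])
    return [m for _, m in masks]


class IndeterminateHomologsError(ValueError):
    """Centromere blobs too similar to call 6A vs 6B for this cell."""


def identify_homologs(
    masks: Sequence[np.ndarray],
    centromere_grid: np.ndarray,
    margin: float = DEFAULT_CENTROMERE_MARGIN,
) -> dict[int, str]:
    """Label the two chromosome masks as 6A/6B by centromere size.

    The homolog whose in-mask centromere signal integrates larger is 6A
    (the larger-centromere chromosome).  If the two integrated signals differ
    by less than ``margin`` (relative), the cell is indeterminate.
    """
    if len(masks) != 2:
        raise ValueError(f"expected exactly 2 chromosome masks, got {len(masks)}")
    cen = np.asarray(centromere_grid, dtype=float)
    totals = [float(cen[m].sum()) for m in masks]
    if min(totals) <= 0:
        raise ValueError("each chromosome mask must contain centromere signal")
    big, small = max(totals), min(totals)
    if (big - small) / big < margin:
        raise IndeterminateHomologsError(
            f"centromere signals within {margin:.0%} of each other: {totals}"
        )
    a_idx = int(np.argmax(totals))
    return {a_idx: "6A", 1 - a_idx: "6B"}


def measure_chromosome(
    mask: np.ndarray,
    brdu_grid: np.ndarray,
    dapi_grid: np.ndarray,
    cell_id: str = "",
    homolog: str = "",
) -> ChromosomeMeasurement:
    """Mean intensities and area over one chromosome mask.

    ``total_brdu`` (mean x area) is identically the pixel sum over the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    brdu = np.asarray(brdu_grid, dtype=float)
    if mask.shape != brdu.shape:
        raise ValueError("mask and grid shapes differ")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return ChromosomeMeasurement(
        cell_id=cell_id,
        homolog=homolog,
        pixel_area=n,
        mean_brdu_intensity=float(brdu[mask].mean()),
        mean_dapi_intensity=float(np.asarray(dapi_grid, dtype=float)[mask].mean()),
    )


def brdu_ratio(
    measurements: Sequence[ChromosomeMeasurement], group: str = ""
) -> BrdUCellRatio:
    """6B/6A total-BrdU ratio for one cell.

    Requires exactly one 6A and one 6B measurement with positive 6A signal.
    """
    by_homolog = {m.homolog: m for m in measurements}
    if set(by_homolog) != {"6A", "6B"} or len(measurements) != 2:
        raise ValueError("need exactly one 6A and one 6B measurement")
    denom = by_homolog["6A"].total_brdu
    if denom <= 0:
        raise ValueError("zero BrdU signal on 6A; cell excluded")
    cell_id = measurements[0].cell_id
    return BrdUCellRatio(cell_id, by_homolog["6B"].total_brdu / denom, group)


def measure_cell_image(
    dapi: np.ndarray,
    brdu: np.ndarray,
    centromere: np.ndarray,
    cell_id: str = "",
    group: str = "",
    background_subtract: bool = True,
    min_area: int = DEFAULT_MIN_AREA,
    margin: float = DEFAULT_CENTROMERE_MARGIN,
) -> BrdUCellRatio:
    """Full image path: segment, identify homologs, measure, form the ratio.

    Background subtraction (default on for images) removes the per-image
    median of non-chromosome BrdU pixels from intensities before totals.
    """
    masks = segment_chromosomes(dapi, min_area=min_area)
    if len(masks) != 2:
        raise ValueError(f"expected 2 chromosomes, segmented {len(masks)}")
    labels = identify_homologs(masks, centromere, margin=margin)
    brdu = np.asarray(brdu, dtype=float)
    if background_subtract:
        outside = ~(masks[0] | masks[1])
        brdu = np.clip(brdu - float(np.median(brdu[outside])), 0.0, None)
    meas = [
        measure_chromosome(masks[i], brdu, dapi, cell_id=cell_id, homolog=labels[i])
        for i in (0, 1)
    ]
    return brdu_ratio(meas, group=group)


# --------------------------------------------------------------------------
# statistics


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis test across genotype groups.

    Mid-ranks over the pooled sample; H divided by the tie correction
    1 - sum(t^3 - t)/(N^3 - N); p from the chi-square upper tail with k-1
    degrees of freedom.  All values identical gives H = 0, p = 1.
    """
    if isinstance(groups, Mapping):
        names = tuple(groups)
        data = [np.asarray(groups[g], dtype=float) for g in names]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        names = tuple(f"group{i+1}" for i in range(len(data)))
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in data):
        raise ValueError("empty group")
    pooled = np.concatenate(data)
    df = len(data) - 1
    if np.unique(pooled).size == 1:
        return GroupComparison(names, tuple(map(len, data)), 0.0, df, 1.0)
    h, p = stats.kruskal(*data)
    return GroupComparison(names, tuple(map(len, data)), float(h), df, float(p))


MEASUREMENT_COLUMNS = ["cell_id", "homolog", "area_px", "mean_brdu", "mean_dapi"]


def read_measurements(path) -> list[ChromosomeMeasurement]:
    """Read pre-extracted workstation measurements from TSV (columns:
    cell_id, homolog, area_px, mean_brdu, mean_dapi)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return [
        ChromosomeMeasurement(
            cell_id=str(r.cell_id),
            homolog=str(r.homolog),
            pixel_area=int(r.area_px),
            mean_brdu_intensity=float(r.mean_brdu),
            mean_dapi_intensity=float(r.mean_dapi),
        )
        for r in df.itertuples(index=False)
    ]
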