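"""Electropherogram peaks to comparable T-RF profiles.

Raw fragment-analyzer output is a list of peaks (size in bp, height in
fluorescence units) per sample and enzyme.  The scoring pipeline is:

1. :func:`filter_peaks` — keep peaks with 50 <= size <= 550 bp and
   height >= 50 FU (inclusive bounds).
2. :func:`normalize` — relative abundance = peak height / cumulative
   height of the sample's retained peaks.
3. :func:`bin_align` — cluster near-identical sizes across samples into
   shared integer bins so profiles become comparable columns.
4. :func:`average_replicates` — mean profile over independent replicate
   samples.

The community matrix is a pandas DataFrame (rows = samples, columns =
integer T-RF bins in increasing order, values = relative abundance, 0
where a bin is absent from a sample).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIZE_MIN",
    "SIZE_MAX",
    "HEIGHT_MIN",
    "MAJOR_TRF_FRACTION",
    "PeakTable",
    "TRFProfile",
    "filter_peaks",
    "normalize",
    "bin_align",
    "average_replicates",
    "richness",
    "major_trfs",
]

logger = logging.getLogger(__name__)

#: Inclusive scoring window for fragment sizes (bp).
SIZE_MIN = 50.0
SIZE_MAX = 550.0
#: Minimum peak height (fluorescence units), inclusive.
HEIGHT_MIN = 50.0
#: A "major" T-RF carries more than this fraction of total abundance.
MAJOR_TRF_FRACTION = 0.05


@dataclass(frozen=True)
class PeakTable:
    """Peaks of one sample under one enzyme (sizes may be fractional bp)."""

    sample_id: str
    enzyme: str
    sizes: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "heights", heights)
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if sizes.shape != heights.shape or sizes.ndim != 1:
            raise ValueError("sizes and heights must be 1-D arrays of equal length")
        if np.any(sizes <= 0):
            raise ValueError("peak sizes must be positive")
        if np.any(heights < 0):
            raise ValueError("peak heights must be non-negative")

    def __len__(self) -> int:
        return self.sizes.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "enzyme": self.enzyme,
                "size_bp": self.sizes,
                "height_fu": self.heights,
            }
        )


@dataclass(frozen=True)
class TRFProfile:
    """Normalized per-sample profile: observed size -> relative abundance.

    Sizes are the observed (possibly fractional) values; integer bin
    labels are only assigned during cross-sample alignment.  ``empty``
    flags a sample with no retained peaks; such profiles are kept so
    sample bookkeeping survives filtering.
    """

    sample_id: str
    enzyme: str
    bins: dict[float, float] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.bins

    def total(self) -> float:
        return float(sum(self.bins.values()))


def filter_peaks(
    raw: PeakTable,
    size_range: tuple[float, float] = (SIZE_MIN, SIZE_MAX),
    min_height: float = HEIGHT_MIN,
) -> PeakTable:
    """Apply the size-window and height-floor thresholds (inclusive bounds).

    Peak order is preserved and the input table is left unmodified.  An
    empty result is legal and logged as a warning.
    """
    lo, hi = size_range
    keep = (raw.sizes >= lo) & (raw.sizes <= hi) & (raw.heights >= min_height)
    out = PeakTable(raw.sample_id, raw.enzyme, raw.sizes[keep], raw.heights[keep])
    if len(out) == 0:
        logger.warning(
            "sample %s (%s): no peaks survive filtering", raw.sample_id, raw.enzyme
        )
    return out


def normalize(filtered: PeakTable) -> TRFProfile:
    """Relative abundance = height / cumulative height of the sample.

    Peaks at identical observed sizes are summed before normalization.
    An empty input yields an empty (flagged) profile, not an error.
    """
    if len(filtered) == 0:
        return TRFProfile(filtered.sample_id, filtered.enzyme, {})
    total = float(filtered.heights.sum())
    bins: dict[float, float] = {}
    for size, height in zip(filtered.sizes, filtered.heights):
        bins[float(size)] = bins.get(float(size), 0.0) + float(height)
    return TRFProfile(
        filtered.sample_id,
        filtered.enzyme,
        {s: h / total for s, h in sorted(bins.items())},
    )


def _single_linkage_bins(
    observations: Sequence[tuple[str, float, float]], tolerance_bp: float
) -> dict[int, list[tuple[str, float]]]:
    """Chain observed sizes into clusters (gap <= tolerance joins) and label
    each cluster with the rounded mean of its member sizes."""
    order = sorted(observations, key=lambda t: t[1])
    clusters: list[list[tuple[str, float, float]]] = []
    for obs in order:
        if clusters and obs[1] - clusters[-1][-1][1] <= tolerance_bp:
            clusters[-1].append(obs)
        else:
            clusters.append([obs])
    out: dict[int, list[tuple[str, float]]] = {}
    for members in clusters:
        label = int(round(float(np.mean([m[1] for m in members]))))
        # two clusters may round to the same integer: merge them
        out.setdefault(label, []).extend((m[0], m[2]) for m in members)
    return out


def bin_align(
    profiles: Iterable[TRFProfile], tolerance_bp: float = 0.5
) -> pd.DataFrame:
    """Align per-sample profiles onto shared integer T-RF bins.

    Observed sizes across all samples are clustered by single linkage:
    consecutive sizes within ``tolerance_bp`` share one bin, labeled by
    the rounded cluster mean.  Within a sample, co-binned abundances are
    summed.  Samples flagged empty become all-zero rows.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to align")
    enzymes = {p.enzyme for p in profiles}
    if len(enzymes) > 1:
        raise ValueError(f"profiles mix enzymes {sorted(enzymes)}; align one enzyme at a time")
    sample_ids = [p.sample_id for p in profiles]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id among profiles")

    observations = [
        (p.sample_id, size, abundance)
        for p in profiles
        for size, abundance in p.bins.items()
    ]
    clusters = _single_linkage_bins(observations, tolerance_bp)
    columns = sorted(clusters)
    matrix = pd.DataFrame(0.0, index=sample_ids, columns=columns)
    for label, members in clusters.items():
        for sample_id, abundance in members:
            matrix.loc[sample_id, label] += abundance
    matrix.index.name = "sample_id"
    matrix.columns.name = "trf_bp"
    return matrix


def average_replicates(
    matrix: pd.DataFrame, replicate_map: Mapping[str, str]
) -> pd.DataFrame:
    """Mean profile per replicate group (e.g. three rhizomes per year/site).

    Every row of ``matrix`` must be mapped to a group; group order follows
    first appearance in the matrix.
    """
    missing = [s for s in matrix.index if s not in replicate_map]
    if missing:
        raise KeyError(f"samples missing from replicate_map: {missing}")
    groups = [replicate_map[s] for s in matrix.index]
    seen: list[str] = []
    for g in groups:
        if g not in seen:
            seen.append(g)
    averaged = matrix.groupby(pd.Series(groups, index=matrix.index)).mean()
    averaged = averaged.loc[seen]
    averaged.index.name = "sample_id"
    averaged.columns.name = matrix.columns.name
    return averaged


def richness(row: "pd.Series | np.ndarray | Sequence[float]") -> int:
    """Number of T-RF bins with strictly positive abundance."""
    return int(np.count_nonzero(np.asarray(row, dtype=float) > 0))


def major_trfs(
    row: pd.Series, fraction: float = MAJOR_TRF_FRACTION
) -> list[int]:
    """Bins carrying more than ``fraction`` of total abundance (reporting aid)."""
    row = row[row > fraction]
    return [int(b) for b in row.index]
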