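"""Post-processing of raw attachment-site calls.

Raw calls from the upstream tiling-array peak caller arrive fragmented:
probes over repetitive sequence are absent from the array, so one physical
attachment region can surface as several nearby intervals.  Calls closer
than a configurable gap (default 2501 bp, i.e. gaps of at most 2500 bp) are
therefore joined transitively.  The joined set is then summarized (size
statistics, coverage of the survey regions) and consecutive intervals
within each survey region yield inter-site distances — an estimator of
chromatin loop size that is right-censored at region boundaries: the flank
of each region beyond the outermost sites, and regions without a pair of
sites, are excluded from the distance analysis and accounted as an excluded
fraction of the surveyed bp.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import (
    GenomicInterval,
    RegionSet,
    assign_to_regions,
    sort_intervals,
)


@dataclass
class SizeSummary:
    n: int
    min_bp: int
    max_bp: int
    mean_bp: float
    median_bp: float
    coverage_fraction: float


@dataclass
class DistanceSummary:
    distances: list[int] = field(default_factory=list)
    min_bp: int | None = None
    max_bp: int | None = None
    mean_bp: float | None = None
    median_bp: float | None = None
    excluded_bp: int = 0
    excluded_fraction: float = 0.0
    n_regions_without_pairs: int = 0


def merge_by_gap(
    intervals: list[GenomicInterval], merge_gap_bp: int
) -> list[GenomicInterval]:
    """Transitively join intervals less than ``merge_gap_bp`` apart.

    Two intervals on the same chromosome are joined when they overlap or
    when the gap between them (start of the later minus end of the earlier)
    is strictly less than ``merge_gap_bp``; a gap of exactly
    ``merge_gap_bp`` is NOT joined.  Output is sorted, non-overlapping,
    with all pairwise gaps >= ``merge_gap_bp``; names of joined inputs are
    concatenated with ','.
    """
    if merge_gap_bp < 1:
        raise ValueError("merge_gap_bp must be >= 1")
    ivs = sort_intervals(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end < merge_gap_bp:
            prev = out[-1]
            names = [n for n in (prev.name, iv.name) if n]
            out[-1] = dataclasses.replace(
                prev,
                end=max(prev.end, iv.end),
                name=",".join(names) if names else None,
            )
        else:
            out.append(iv)
    return out


def size_summary(
    intervals: list[GenomicInterval], regions: RegionSet
) -> SizeSummary:
    """Length statistics of an interval set plus coverage of the regions.

    The median of an even count is the mean of the two central values;
    coverage is summed interval length over the regions' total bp (the
    intervals are expected non-overlapping, i.e. already gap-joined).
    """
    if not intervals:
        raise ValueError("size_summary: empty interval set")
    lengths = np.array([iv.length for iv in intervals], dtype=np.int64)
    return SizeSummary(
        n=len(lengths),
        min_bp=int(lengths.min()),
        max_bp=int(lengths.max()),
        mean_bp=float(lengths.mean()),
        median_bp=float(np.median(lengths)),
        coverage_fraction=float(lengths.sum() / regions.total_bp),
    )


def inter_interval_distances(
    intervals: list[GenomicInterval],
    regions: RegionSet,
    endpoint: str = "gap",
) -> DistanceSummary:
    """Distances between consecutive intervals within each survey region.

    For each region holding >= 2 intervals, consecutive pairs contribute
    ``start(i+1) - end(i)`` — the loop DNA between attachment sites
    (``endpoint='midpoint'`` measures midpoint-to-midpoint instead).  Flanks
    from the region edge to the outermost interval are censored: their bp,
    plus the full length of regions with no interval and both flanks of
    single-interval regions, accumulate into ``excluded_fraction`` over the
    regions' total bp.
    """
    if endpoint not in ("gap", "midpoint"):
        raise ValueError(f"unknown endpoint convention {endpoint!r}")
    assignment = assign_to_regions(intervals, regions)
    distances: list[int] = []
    excluded_bp = 0
    n_without_pairs = 0
    for ridx, region in enumerate(regions):
        ivs = assignment.by_region[ridx]
        if not ivs:
            excluded_bp += region.length
            n_without_pairs += 1
            continue
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals {a} and {b}: run merge_by_gap first"
                )
            if endpoint == "gap":
                distances.append(b.start - a.end)
            else:
                distances.append(
                    (b.start + b.end) // 2 - (a.start + a.end) // 2
                )
        if len(ivs) == 1:
            n_without_pairs += 1
        excluded_bp += (ivs[0].start - region.start) + (region.end - ivs[-1].end)
    summary = DistanceSummary(
        distances=distances,
        excluded_bp=excluded_bp,
        excluded_fraction=excluded_bp / regions.total_bp,
        n_regions_without_pairs=n_without_pairs,
    )
    if distances:
        arr = np.asarray(distances, dtype=np.int64)
        summary.min_bp = int(arr.min())
        summary.max_bp = int(arr.max())
        summary.mean_bp = float(arr.mean())
        summary.median_bp = float(np.median(arr))
    return summary


def length_histogram(
    intervals: list[GenomicInterval], bin_bp: int = 2000
) -> pd.DataFrame:
    """Interval-length histogram in fixed-width bins (default 2 kb)."""
    lengths = np.array([iv.length for iv in intervals], dtype=np.int64)
    return _binned(lengths, bin_bp)


def distance_histogram(distances: list[int], bin_bp: int = 25_000) -> pd.DataFrame:
    """Inter-interval distance histogram in fixed-width bins (default 25 kb)."""
    return _binned(np.asarray(distances, dtype=np.int64), bin_bp)


def _binned(values: np.ndarray, bin_bp: int) -> pd.DataFrame:
    if bin_bp <= 0:
        raise ValueError("bin width must be positive")
    if values.size == 0:
        return pd.DataFrame({"bin_start_bp": [], "bin_end_bp": [], "count": []})
    n_bins = int(values.max() // bin_bp) + 1
    edges = np.arange(0, (n_bins + 1) * bin_bp, bin_bp)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {
            "bin_start_bp": edges[:-1].astype(int),
            "bin_end_bp": edges[1:].astype(int),
            "count": counts.astype(int),
        }
    )
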