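"""Gene-centric context of the query intervals.

Derives point tracks for transcription start/end sites (TSS/TES), profiles
the signed distance from each query interval to its nearest such point
within the same survey region, classifies query bp into gene body /
5-kb-upstream / intergenic classes, and reports gene-proximity percentages
stratified by the expressed flag.

Sign convention for nearest-point distances: 0 on overlap; otherwise the
gap bp between the query and the point, positive when the query lies
DOWNSTREAM of the point in the point's strand orientation and negative
when it lies upstream (configurable via ``orientation='genomic'``, which
signs by genomic left/right instead).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import (
    FeatureTrack,
    GeneModel,
    GenomicInterval,
    RegionSet,
    assign_to_regions,
    sort_intervals,
)
from .enrichment_engine import (
    GlobalFrame,
    OverlapStatistic,
    TargetIndex,
)


@dataclass
class GeneContextReport:
    n_query: int
    pct_within_of_gene: float
    pct_within_of_expressed_gene: float
    proximity_bp: int
    genic_bp: int
    upstream_bp: int
    intergenic_bp: int
    pct_genic: float
    pct_upstream: float
    pct_intergenic: float
    background_pct_genic: float
    background_pct_upstream: float
    background_pct_intergenic: float
    upstream_window_bp: int = 5000


def derive_point_track(
    genes: list[GeneModel], which: str = "tss"
) -> FeatureTrack:
    """One 1-bp interval per gene at the strand-aware 5' (tss) or 3' (tes)
    end; duplicate points (shared by isoforms) are collapsed."""
    if which not in ("tss", "tes"):
        raise ValueError(f"which must be 'tss' or 'tes', got {which!r}")
    seen: set[tuple[str, int, str]] = set()
    points: list[GenomicInterval] = []
    for g in genes:
        pos = g.tss if which == "tss" else g.tes
        key = (g.body.chrom, pos, g.body.strand)
        if key in seen:
            continue
        seen.add(key)
        points.append(
            GenomicInterval(
                g.body.chrom, pos, pos + 1,
                name=g.body.name, strand=g.body.strand,
                flags={"expressed": g.expressed},
            )
        )
    return FeatureTrack(which, sort_intervals(points))


def nearest_signed_distances(
    query: list[GenomicInterval],
    points: FeatureTrack,
    regions: RegionSet,
    orientation: str = "strand",
) -> tuple[np.ndarray, int]:
    """Signed distance from each query to its nearest point in its region.

    Returns (distances for queries with a reachable point, number of queries
    excluded because their region holds no point).  Ties between an up- and
    a downstream point at equal distance resolve to the downstream one.
    """
    if orientation not in ("strand", "genomic"):
        raise ValueError(f"unknown orientation {orientation!r}")
    q_assign = assign_to_regions(query, regions)
    p_assign = assign_to_regions(points.elements, regions)
    distances: list[int] = []
    n_excluded = 0
    for ridx in range(len(regions)):
        qs = q_assign.by_region[ridx]
        ps = p_assign.by_region[ridx]
        if not qs:
            continue
        if not ps:
            n_excluded += len(qs)
            continue
        starts = np.array([p.start for p in ps])
        strands = np.array([1 if p.strand != "-" else -1 for p in ps])
        for q in qs:
            # gap bp from the query to each candidate point (0 on overlap)
            d = np.where(
                (starts >= q.start) & (starts < q.end),
                0,
                np.where(starts >= q.end, starts - q.end, q.start - (starts + 1)),
            )
            point_is_right = starts >= q.end
            if orientation == "genomic":
                downstream = point_is_right
            else:
                downstream = np.where(strands > 0, point_is_right, ~point_is_right)
            # nearest point wins; equal-distance ties resolve downstream (+)
            best = int(np.lexsort((~downstream, d))[0])
            dist = int(d[best])
            if dist == 0:
                distances.append(0)
            else:
                distances.append(dist if downstream[best] else -dist)
    return np.asarray(distances, dtype=np.int64), n_excluded


def nearest_distance_profile(
    query: list[GenomicInterval],
    points: FeatureTrack,
    regions: RegionSet,
    bins: np.ndarray | list[int],
    orientation: str = "strand",
) -> pd.DataFrame:
    """Histogram of signed nearest-point distances over the given bin edges."""
    bins = np.asarray(bins)
    if len(bins) < 2 or (np.diff(bins) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    distances, _ = nearest_signed_distances(query, points, regions, orientation)
    counts, edges = np.histogram(distances, bins=bins)
    return pd.DataFrame(
        {
            "bin_start_bp": edges[:-1].astype(int),
            "bin_end_bp": edges[1:].astype(int),
            "count": counts.astype(int),
        }
    )


def _merged_cov(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(cover: list[tuple[int, int]], minus: list[tuple[int, int]]):
    """Set difference of two merged interval lists."""
    out = []
    j = 0
    for s, e in cover:
        cur = s
        while j < len(minus) and minus[j][1] <= cur:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < e:
            ms, me = minus[k]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _bp_in(index: TargetIndex, qs: np.ndarray, qe: np.ndarray) -> int:
    return int(index.intersect_bp(qs, qe).sum())


def genic_breakdown(
    query: list[GenomicInterval],
    genes: list[GeneModel],
    regions: RegionSet,
    upstream_bp: int = 5000,
    proximity_bp: int = 5000,
) -> GeneContextReport:
    """Classify query bp into gene body / upstream window / intergenic.

    Priority: gene body > ``upstream_bp`` upstream of the TSS > intergenic;
    overlapping gene bodies are unioned so no bp is counted twice.  The same
    breakdown over the whole region set is reported as the background.
    Also reports the fraction of query intervals within ``proximity_bp`` of
    a gene (all genes and expressed genes).
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    assignment = assign_to_regions(query, regions)
    used = assignment.assigned
    if not used:
        raise ValueError("no query interval lies wholly within the regions")
    frame = GlobalFrame(regions)
    qs, qe = frame.project(used, assignment.region_index)

    bodies = FeatureTrack("genic", [g.body for g in genes]).clipped_to(regions)
    upstreams = []
    for g in genes:
        if g.body.strand == "+":
            s, e = g.body.start - upstream_bp, g.body.start
        else:
            s, e = g.body.end, g.body.end + upstream_bp
        s = max(s, 0)
        if e > s:
            upstreams.append(GenomicInterval(g.body.chrom, s, e))
    upstream_track = FeatureTrack("upstream", upstreams).clipped_to(regions)

    gb_s, gb_e = frame.project_track(bodies)
    up_s, up_e = frame.project_track(upstream_track)
    genic_cov = _merged_cov(list(zip(gb_s.tolist(), gb_e.tolist())))
    up_cov = _subtract(
        _merged_cov(list(zip(up_s.tolist(), up_e.tolist()))), genic_cov
    )
    genic_ix = TargetIndex(
        np.array([s for s, _ in genic_cov], dtype=np.int64),
        np.array([e for _, e in genic_cov], dtype=np.int64),
    )
    up_ix = TargetIndex(
        np.array([s for s, _ in up_cov], dtype=np.int64),
        np.array([e for _, e in up_cov], dtype=np.int64),
    )
    total_q_bp = int((qe - qs).sum())
    q_genic = _bp_in(genic_ix, qs, qe)
    q_up = _bp_in(up_ix, qs, qe)
    q_inter = total_q_bp - q_genic - q_up

    bg_genic = sum(e - s for s, e in genic_cov)
    bg_up = sum(e - s for s, e in up_cov)
    bg_total = regions.total_bp
    bg_inter = bg_total - bg_genic - bg_up

    prox = OverlapStatistic("within_distance", proximity_bp)
    body_index = TargetIndex(gb_s, gb_e)
    n_near = int(body_index.per_query(qs, qe, prox).sum())
    expressed_bodies = FeatureTrack(
        "expressed", [g.body for g in genes if g.expressed]
    ).clipped_to(regions)
    ex_s, ex_e = frame.project_track(expressed_bodies)
    n_near_ex = int(TargetIndex(ex_s, ex_e).per_query(qs, qe, prox).sum())

    n = len(used)
    return GeneContextReport(
        n_query=n,
        pct_within_of_gene=100.0 * n_near / n,
        pct_within_of_expressed_gene=100.0 * n_near_ex / n,
        proximity_bp=proximity_bp,
        genic_bp=q_genic,
        upstream_bp=q_up,
        intergenic_bp=q_inter,
        pct_genic=100.0 * q_genic / total_q_bp,
        pct_upstream=100.0 * q_up / total_q_bp,
        pct_intergenic=100.0 * q_inter / total_q_bp,
        background_pct_genic=100.0 * bg_genic / bg_total,
        background_pct_upstream=100.0 * bg_up / bg_total,
        background_pct_intergenic=100.0 * bg_inter / bg_total,
        upstream_window_bp=upstream_bp,
    )
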