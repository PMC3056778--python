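"""Region-constrained randomization enrichment testing.

The central statistic of the pipeline: a query interval set (the attachment
sites) is compared to a target feature track through one of four overlap
statistics, and significance is assessed against an empirical null obtained
by re-placing the query intervals uniformly at random inside the bounded
survey regions.  The null preserves exactly the number of query intervals
and their multiset of lengths; each randomized interval is placed wholly
within a region chosen with probability proportional to its number of
eligible start positions (region length − interval length + 1), with the
start uniform over those positions.  Randomized intervals may overlap one
another.  No analytic approximation is used: P values are empirical with
the add-one (permutation-inclusive) estimator, so the smallest attainable
P at N randomizations is 1/(N+1) — 0.0001 at N = 9999.

Overlap statistics
------------------
count            number of query intervals sharing >= 1 bp with any target
within_distance  number of query intervals whose nearest target boundary is
                 <= distance_bp away (0 means direct overlap)
containment      number of query intervals fully containing >= 1 target
bp               total intersection bp between the query set and the
                 union of the targets

Internally all interval arithmetic runs on a single int64 axis: survey
regions (or chromosomes) are laid end-to-end with large guard gaps, which
makes every statistic a couple of ``searchsorted`` calls and keeps the
9999-randomization loop vectorized.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .genome_model import (
    FeatureTrack,
    GenomicInterval,
    RegionSet,
    assign_to_regions,
    sort_intervals,
)

_GUARD = 1 << 33  # separation between linearized regions; blocks any
                  # cross-region overlap or within-distance leakage


# ---------------------------------------------------------------------------
# Statistic definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapStatistic:
    mode: str = "count"
    distance_bp: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("count", "within_distance", "containment", "bp"):
            raise ValueError(f"unknown overlap mode {self.mode!r}")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")


@dataclass
class EnrichmentResult:
    """Observed statistic, null summary and empirical P values for one track."""

    track_name: str
    mode: str
    distance_bp: int
    observed: float
    null_mean: float
    null_median: float
    null_sd: float
    n_randomizations: int
    p_enrich: float
    p_deplete: float
    enrichment_pct: float
    enrichment_defined: bool
    n_query_used: int
    n_query_excluded: int
    null_values: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Target index: vectorized overlap kernels on one int64 axis
# ---------------------------------------------------------------------------

class TargetIndex:
    """Sorted/merged target intervals with O(log m) per-query kernels."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        self.raw_starts = starts[order]
        self.raw_ends = ends[order]
        self.m = len(starts)
        if self.m:
            run_end = np.maximum.accumulate(self.raw_ends)
            is_new = np.concatenate(([True], self.raw_starts[1:] > run_end[:-1]))
            firsts = np.flatnonzero(is_new)
            lasts = np.concatenate((firsts[1:] - 1, [self.m - 1]))
            self.merged_starts = self.raw_starts[firsts]
            self.merged_ends = run_end[lasts]
            cov = self.merged_ends - self.merged_starts
            self.cumcov = np.concatenate(([0], np.cumsum(cov)))
            # sparse table of range-minimum over raw ends (containment mode)
            self._sparse = [self.raw_ends]
            k = 1
            while (1 << k) <= self.m:
                prev = self._sparse[-1]
                half = 1 << (k - 1)
                self._sparse.append(np.minimum(prev[:-half], prev[half:]))
                k += 1
        else:
            self.merged_starts = np.empty(0, dtype=np.int64)
            self.merged_ends = np.empty(0, dtype=np.int64)
            self.cumcov = np.zeros(1, dtype=np.int64)
            self._sparse = []

    def any_overlap(self, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Boolean per query: shares >= 1 bp with any target."""
        if not self.m:
            return np.zeros(qs.shape, dtype=bool)
        i = np.searchsorted(self.merged_ends, qs, side="right")
        ok = i < len(self.merged_starts)
        hit = np.zeros(qs.shape, dtype=bool)
        hit[ok] = self.merged_starts[i[ok]] < qe[ok]
        return hit

    def within_distance(self, qs, qe, distance_bp: int) -> np.ndarray:
        """Boolean per query: nearest target boundary <= distance_bp away.

        distance 0 means direct overlap (a book-ended target does not
        count); at d > 0 a gap of exactly d bp counts.
        """
        if not self.m:
            return np.zeros(qs.shape, dtype=bool)
        if distance_bp == 0:
            return self.any_overlap(qs, qe)
        i = np.searchsorted(self.merged_ends, qs - distance_bp, side="left")
        ok = i < len(self.merged_starts)
        hit = np.zeros(qs.shape, dtype=bool)
        hit[ok] = self.merged_starts[i[ok]] <= qe[ok] + distance_bp
        return hit

    def _range_min_end(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """min(raw_ends[lo:hi]) vectorized; caller guarantees hi > lo."""
        w = hi - lo
        k = np.floor(np.log2(w)).astype(np.int64)
        res = np.empty(lo.shape, dtype=np.int64)
        for kk in np.unique(k):
            mask = k == kk
            tab = self._sparse[kk]
            span = 1 << int(kk)
            res[mask] = np.minimum(tab[lo[mask]], tab[hi[mask] - span])
        return res

    def contained_in(self, qs, qe) -> np.ndarray:
        """Boolean per query: fully contains >= 1 individual target element."""
        if not self.m:
            return np.zeros(qs.shape, dtype=bool)
        lo = np.searchsorted(self.raw_starts, qs, side="left")
        hi = np.searchsorted(self.raw_starts, qe, side="left")
        hit = np.zeros(qs.shape, dtype=bool)
        nonempty = hi > lo
        if nonempty.any():
            min_end = self._range_min_end(lo[nonempty], hi[nonempty])
            hit[nonempty] = min_end <= qe[nonempty]
        return hit

    def intersect_bp(self, qs, qe) -> np.ndarray:
        """Intersection bp per query with the union of the targets."""
        if not self.m:
            return np.zeros(qs.shape, dtype=np.int64)
        i0 = np.searchsorted(self.merged_ends, qs, side="right")
        i1 = np.searchsorted(self.merged_starts, qe, side="left")
        out = np.zeros(qs.shape, dtype=np.int64)
        has = i1 > i0
        if has.any():
            a, b = qs[has], qe[has]
            j0, j1 = i0[has], i1[has]
            total = self.cumcov[j1] - self.cumcov[j0]
            left_clip = np.maximum(a - self.merged_starts[j0], 0)
            right_clip = np.maximum(self.merged_ends[j1 - 1] - b, 0)
            out[has] = total - left_clip - right_clip
        return out

    def per_query(self, qs, qe, stat: OverlapStatistic) -> np.ndarray:
        if stat.mode == "count":
            return self.any_overlap(qs, qe)
        if stat.mode == "within_distance":
            return self.within_distance(qs, qe, stat.distance_bp)
        if stat.mode == "containment":
            return self.contained_in(qs, qe)
        if stat.mode == "bp":
            return self.intersect_bp(qs, qe)
        raise ValueError(f"unknown overlap mode {stat.mode!r}")


# ---------------------------------------------------------------------------
# Linearization helpers
# ---------------------------------------------------------------------------

class GlobalFrame:
    """Survey regions laid end-to-end on one int64 axis with guard gaps."""

    def __init__(self, regions: RegionSet):
        self.regions = regions
        self.region_lengths = np.array([r.length for r in regions], dtype=np.int64)
        self.offsets = np.concatenate(
            ([0], np.cumsum(self.region_lengths[:-1] + _GUARD))
        ).astype(np.int64)
        self.region_starts = np.array([r.start for r in regions], dtype=np.int64)

    def project(
        self, intervals: list[GenomicInterval], region_index: list[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        ridx = np.asarray(region_index, dtype=np.int64)
        starts = np.array([iv.start for iv in intervals], dtype=np.int64)
        ends = np.array([iv.end for iv in intervals], dtype=np.int64)
        gs = self.offsets[ridx] + (starts - self.region_starts[ridx])
        return gs, gs + (ends - starts)

    def project_track(self, track: FeatureTrack) -> tuple[np.ndarray, np.ndarray]:
        clipped = track.clipped_to(self.regions)
        if not clipped.elements:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        assignment = assign_to_regions(clipped.elements, self.regions)
        return self.project(assignment.assigned, assignment.region_index)

    def lift(
        self,
        gstarts: np.ndarray,
        lengths: np.ndarray,
        ridx: np.ndarray,
        names: list[str | None] | None = None,
    ) -> list[GenomicInterval]:
        starts = self.region_starts[ridx] + (gstarts - self.offsets[ridx])
        out = []
        for i in range(len(gstarts)):
            out.append(
                GenomicInterval(
                    self.regions[int(ridx[i])].chrom,
                    int(starts[i]),
                    int(starts[i] + lengths[i]),
                    name=names[i] if names else None,
                )
            )
        return out


def _linearize_by_chrom(
    *interval_sets: list[GenomicInterval],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Project interval sets onto one axis, chromosomes separated by guards."""
    chroms = sorted({iv.chrom for ivs in interval_sets for iv in ivs})
    span: dict[str, int] = {c: 0 for c in chroms}
    for ivs in interval_sets:
        for iv in ivs:
            span[iv.chrom] = max(span[iv.chrom], iv.end)
    offsets: dict[str, int] = {}
    pos = 0
    for c in chroms:
        offsets[c] = pos
        pos += span[c] + _GUARD
    out = []
    for ivs in interval_sets:
        gs = np.array([offsets[iv.chrom] + iv.start for iv in ivs], dtype=np.int64)
        ge = np.array([offsets[iv.chrom] + iv.end for iv in ivs], dtype=np.int64)
        out.append((gs, ge))
    return out


# ---------------------------------------------------------------------------
# Public statistic
# ---------------------------------------------------------------------------

def overlap_statistic(
    query: list[GenomicInterval],
    targets: FeatureTrack | list[GenomicInterval],
    stat: OverlapStatistic,
) -> float:
    """Evaluate one overlap statistic between a query set and a target set.

    Chromosome-aware; each query interval is counted at most once for the
    count/within_distance/containment modes.
    """
    t_elements = targets.elements if isinstance(targets, FeatureTrack) else targets
    if not query:
        return 0.0
    (qs, qe), (ts, te) = _linearize_by_chrom(list(query), list(t_elements))
    index = TargetIndex(ts, te)
    return float(index.per_query(qs, qe, stat).sum())


# ---------------------------------------------------------------------------
# Randomization null
# ---------------------------------------------------------------------------

class QueryRandomizer:
    """Vectorized placement of fixed-length intervals inside the regions.

    Placement law: region chosen with probability proportional to its count
    of eligible start positions for the interval's length, start uniform
    over those; ``keep_region`` instead confines each interval to its source
    region (sensitivity-analysis variant).
    """

    def __init__(
        self,
        lengths: np.ndarray,
        frame: GlobalFrame,
        keep_region: bool = False,
        source_region: np.ndarray | None = None,
    ):
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.frame = frame
        elig = frame.region_lengths[None, :] - self.lengths[:, None] + 1
        np.clip(elig, 0, None, out=elig)
        if keep_region:
            if source_region is None:
                raise ValueError("keep_region requires source_region indices")
            mask = np.zeros_like(elig)
            rows = np.arange(len(self.lengths))
            mask[rows, np.asarray(source_region, dtype=np.int64)] = 1
            elig = elig * mask
        self.cum = np.cumsum(elig, axis=1)
        self.total = self.cum[:, -1]
        if (self.total == 0).any():
            bad = int(np.flatnonzero(self.total == 0)[0])
            raise ValueError(
                f"interval #{bad} (length {int(self.lengths[bad])} bp) does not "
                "fit in any eligible region"
            )
        self.cum_prev = np.concatenate(
            (np.zeros((len(self.lengths), 1), dtype=np.int64), self.cum[:, :-1]),
            axis=1,
        )
        # strict upper bound for the uniform draw so ridx never runs past
        # the last region with eligible positions
        self._u_max = np.nextafter(self.total.astype(np.float64), 0.0)

    def draw_global(
        self, rng: np.random.Generator, n_draws: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw placements; returns (global starts, region index), each (d, n)."""
        u = rng.random((n_draws, len(self.lengths))) * self.total[None, :]
        np.minimum(u, self._u_max[None, :], out=u)
        ridx = (u[:, :, None] >= self.cum[None, :, :]).sum(axis=2)
        base = np.take_along_axis(
            np.broadcast_to(self.cum_prev[None], (n_draws,) + self.cum_prev.shape),
            ridx[:, :, None],
            axis=2,
        )[:, :, 0]
        local = np.floor(u - base).astype(np.int64)
        # guard against pathological float rounding at the cell edge
        cell = np.take_along_axis(
            np.broadcast_to(self.cum[None], (n_draws,) + self.cum.shape),
            ridx[:, :, None],
            axis=2,
        )[:, :, 0] - base
        np.clip(local, 0, cell - 1, out=local)
        gstart = self.frame.offsets[ridx] + local
        return gstart, ridx


def randomize_query(
    query: list[GenomicInterval],
    regions: RegionSet,
    rng: np.random.Generator | int,
    keep_region: bool = False,
) -> list[GenomicInterval]:
    """One randomized replicate of the query set (count and lengths preserved)."""
    rng = np.random.default_rng(rng)
    assignment = assign_to_regions(query, regions)
    ivs = assignment.assigned
    if len(ivs) != len(query):
        raise ValueError(
            "randomize_query: every query interval must lie wholly within a region"
        )
    frame = GlobalFrame(regions)
    lengths = np.array([iv.length for iv in ivs], dtype=np.int64)
    randomizer = QueryRandomizer(
        lengths,
        frame,
        keep_region=keep_region,
        source_region=np.asarray(assignment.region_index) if keep_region else None,
    )
    gstart, ridx = randomizer.draw_global(rng, 1)
    return frame.lift(gstart[0], lengths, ridx[0],
                      names=[iv.name for iv in ivs])


# ---------------------------------------------------------------------------
# Empirical P and the tests
# ---------------------------------------------------------------------------

def empirical_p(null: np.ndarray, observed: float) -> tuple[float, float]:
    """Add-one empirical P values; ties count as significant in both tails."""
    n = len(null)
    p_enrich = (1 + int((null >= observed).sum())) / (1 + n)
    p_deplete = (1 + int((null <= observed).sum())) / (1 + n)
    return p_enrich, p_deplete


def track_seed(master_seed: int, track_name: str) -> np.random.SeedSequence:
    """Stable per-track child stream: adding a track never shifts another's."""
    digest = hashlib.sha256(track_name.encode("utf-8")).digest()
    child = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence(entropy=[int(master_seed), child])


def _summarize(
    track_name: str,
    stat: OverlapStatistic,
    observed: float,
    null: np.ndarray,
    n_used: int,
    n_excluded: int,
) -> EnrichmentResult:
    p_enrich, p_deplete = empirical_p(null, observed)
    null_mean = float(null.mean())
    defined = null_mean > 0
    pct = 100.0 * (observed - null_mean) / null_mean if defined else float("nan")
    return EnrichmentResult(
        track_name=track_name,
        mode=stat.mode,
        distance_bp=stat.distance_bp,
        observed=float(observed),
        null_mean=null_mean,
        null_median=float(np.median(null)),
        null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
        n_randomizations=len(null),
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        enrichment_pct=pct,
        enrichment_defined=defined,
        n_query_used=n_used,
        n_query_excluded=n_excluded,
        null_values=null,
    )


def enrichment_test(
    query: list[GenomicInterval],
    targets: FeatureTrack | list[GenomicInterval],
    regions: RegionSet,
    stat: OverlapStatistic | None = None,
    n_randomizations: int = 9999,
    rng_seed: int | np.random.Generator | np.random.SeedSequence = 0,
    keep_region: bool = False,
    chunk_size: int = 512,
) -> EnrichmentResult:
    """Region-constrained randomization test of query/target association.

    The observed statistic is compared with ``n_randomizations`` replicates
    of the query set re-placed inside the regions; the same seed gives
    bit-identical results.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    if not isinstance(targets, FeatureTrack):
        targets = FeatureTrack("targets", list(targets))
    if stat is None:
        stat = OverlapStatistic(targets.overlap_mode, targets.distance_bp)
    rng = np.random.default_rng(rng_seed)

    assignment = assign_to_regions(query, regions)
    used = assignment.assigned
    n_excluded = len(assignment.straddling) + len(assignment.outside)
    if not used:
        raise ValueError("no query interval lies wholly within the regions")
    frame = GlobalFrame(regions)
    qs, qe = frame.project(used, assignment.region_index)
    lengths = qe - qs
    ts, te = frame.project_track(targets)
    index = TargetIndex(ts, te)

    observed = float(index.per_query(qs, qe, stat).sum())

    randomizer = QueryRandomizer(
        lengths,
        frame,
        keep_region=keep_region,
        source_region=np.asarray(assignment.region_index) if keep_region else None,
    )
    null = np.empty(n_randomizations, dtype=np.float64)
    done = 0
    while done < n_randomizations:
        d = min(chunk_size, n_randomizations - done)
        gstart, _ = randomizer.draw_global(rng, d)
        flat_s = gstart.ravel()
        flat_e = flat_s + np.tile(lengths, d)
        vals = index.per_query(flat_s, flat_e, stat).reshape(d, -1).sum(axis=1)
        null[done : done + d] = vals
        done += d
    return _summarize(targets.track_name, stat, observed, null, len(used), n_excluded)


def reciprocal_test(
    query: list[GenomicInterval],
    targets: FeatureTrack | list[GenomicInterval],
    regions: RegionSet,
    stat: OverlapStatistic | None = None,
    n_randomizations: int = 9999,
    rng_seed: int | np.random.Generator | np.random.SeedSequence = 0,
    keep_region: bool = False,
    chunk_size: int = 512,
) -> EnrichmentResult:
    """Same machinery with query and target roles exchanged.

    The target set (clipped to the regions) becomes the randomized set and
    the original query becomes the fixed track: e.g. "what fraction of
    CTCF sites fall on an attachment site" rather than the converse.
    """
    if not isinstance(targets, FeatureTrack):
        targets = FeatureTrack("targets", list(targets))
    if stat is None:
        stat = OverlapStatistic(targets.overlap_mode, targets.distance_bp)
    clipped = targets.clipped_to(regions)
    query_track = FeatureTrack(
        f"{targets.track_name}|reciprocal", sort_intervals(query),
        stat.mode, stat.distance_bp,
    )
    return enrichment_test(
        clipped.elements,
        query_track,
        regions,
        stat=stat,
        n_randomizations=n_randomizations,
        rng_seed=rng_seed,
        keep_region=keep_region,
        chunk_size=chunk_size,
    )


def class_overlap_test(
    query: list[GenomicInterval],
    class_tracks: list[FeatureTrack],
    regions: RegionSet,
    n_randomizations: int = 9999,
    rng_seed: int | np.random.Generator | np.random.SeedSequence = 0,
    keep_region: bool = False,
    chunk_size: int = 512,
) -> list[EnrichmentResult]:
    """bp-overlap enrichment against several class tracks (e.g. replication
    timing early/mid/late) from a SHARED set of randomizations, so results
    across classes are directly comparable."""
    rng = np.random.default_rng(rng_seed)
    stat = OverlapStatistic("bp")
    assignment = assign_to_regions(query, regions)
    used = assignment.assigned
    n_excluded = len(assignment.straddling) + len(assignment.outside)
    if not used:
        raise ValueError("no query interval lies wholly within the regions")
    frame = GlobalFrame(regions)
    qs, qe = frame.project(used, assignment.region_index)
    lengths = qe - qs

    indexes = []
    for track in class_tracks:
        ts, te = frame.project_track(track)
        indexes.append(TargetIndex(ts, te))
    observed = [float(ix.intersect_bp(qs, qe).sum()) for ix in indexes]

    randomizer = QueryRandomizer(
        lengths,
        frame,
        keep_region=keep_region,
        source_region=np.asarray(assignment.region_index) if keep_region else None,
    )
    null = np.empty((len(class_tracks), n_randomizations), dtype=np.float64)
    done = 0
    while done < n_randomizations:
        d = min(chunk_size, n_randomizations - done)
        gstart, _ = randomizer.draw_global(rng, d)
        flat_s = gstart.ravel()
        flat_e = flat_s + np.tile(lengths, d)
        for ci, ix in enumerate(indexes):
            null[ci, done : done + d] = (
                ix.intersect_bp(flat_s, flat_e).reshape(d, -1).sum(axis=1)
            )
        done += d
    return [
        _summarize(track.track_name, stat, observed[ci], null[ci], len(used), n_excluded)
        for ci, track in enumerate(class_tracks)
    ]
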