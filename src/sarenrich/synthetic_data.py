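"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
bounded survey space of 44 regions (thirty pinned at the 0.5 Mb range
minimum plus fourteen drawn uniformly up to 2 Mb, mirroring the mixed
design of the real pilot-region set, ~30 Mb in total), 453 query intervals
with a log-normal length law (median 3423 bp, ln-scale sd 0.8331 chosen so
the mean matches ~4.8 kb, floored at 1024 bp to emulate the upstream peak
caller's 1-kb window), target tracks with tunable planted co-location,
sequences with elevated AT inside the query intervals, and a qPCR panel
with a log-linear standard-curve response.

Planted-association model: each target independently is placed, with
probability pi, to overlap a uniformly chosen query interval (start
uniform over the positions guaranteeing >= 1 bp overlap inside the
region); with probability 1-pi it follows the null placement law of the
enrichment engine.  The expected count-overlap statistic of this mixture
has a closed form (per-target miss probabilities including incidental
overlaps of force-placed targets with other queries), so the generator can
emit an analytic oracle next to the data.  Every generator is a pure
function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    FeatureTrack,
    GeneModel,
    GenomicInterval,
    RegionSet,
    assign_to_regions,
    write_bed,
)
from .enrichment_engine import GlobalFrame, QueryRandomizer, track_seed

# stage tags: distinct child streams per generator so regenerating one
# artifact never perturbs another
_STAGE = {
    "regions": 1, "queries": 2, "sar_like": 3, "targets": 4,
    "sequences": 5, "qpcr": 6, "genes": 7, "classes": 8,
}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic pipeline."""

    n_regions: int = 44
    region_length_range: tuple[int, int] = (500_000, 2_000_000)
    n_minimal_regions: int = 30   # regions pinned at the range minimum
    n_queries: int = 453
    query_median_bp: float = 3423.0
    query_sigma_log: float = 0.8331
    query_min_bp: int = 1024
    n_targets: int = 400
    target_length_bp: int = 500
    colocation_prob: float = 0.5
    at_background: float = 0.50
    at_query: float = 0.65
    qpcr_slope: float = -3.32
    qpcr_intercept: float = 30.0
    qpcr_noise_sd: float = 0.1
    qpcr_true_enrichment: float = 5.0
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.colocation_prob <= 1.0:
            raise ValueError("colocation_prob must be in [0, 1]")
        for frac in (self.at_background, self.at_query):
            if not 0.0 < frac < 1.0:
                raise ValueError("AT fractions must be in (0, 1)")
        for count in (self.n_regions, self.n_queries, self.n_targets):
            if count < 1:
                raise ValueError("counts must be positive")
        lo, hi = self.region_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid region length range")
        if self.n_minimal_regions > self.n_regions:
            raise ValueError("n_minimal_regions cannot exceed n_regions")


def _rng(spec: SyntheticSpec, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[int(spec.rng_seed), _STAGE[stage]])
    )


# ---------------------------------------------------------------------------
# Regions and queries
# ---------------------------------------------------------------------------

def generate_regions(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> RegionSet:
    """Non-overlapping survey regions, one per synthetic chromosome.

    ``n_minimal_regions`` regions take the range minimum; the rest are
    uniform in ``region_length_range`` (set ``n_minimal_regions=0`` for a
    purely uniform law).
    """
    rng = rng if rng is not None else _rng(spec, "regions")
    lo, hi = spec.region_length_range
    n_uniform = spec.n_regions - spec.n_minimal_regions
    lengths = np.concatenate(
        [
            np.full(spec.n_minimal_regions, lo, dtype=np.int64),
            rng.integers(lo, hi + 1, size=n_uniform, dtype=np.int64),
        ]
    )
    rng.shuffle(lengths)
    starts = rng.integers(10_000, 50_000, size=spec.n_regions)
    regions = [
        GenomicInterval(
            f"chr{i + 1:02d}",
            int(starts[i]),
            int(starts[i] + lengths[i]),
            name=f"region_{i + 1:02d}",
        )
        for i in range(spec.n_regions)
    ]
    return RegionSet(regions)


def _query_lengths(spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    raw = rng.lognormal(
        mean=math.log(spec.query_median_bp), sigma=spec.query_sigma_log, size=n
    )
    return np.maximum(np.round(raw).astype(np.int64), spec.query_min_bp)


def generate_query_set(
    spec: SyntheticSpec,
    regions: RegionSet,
    rng: np.random.Generator | None = None,
    n: int | None = None,
) -> list[GenomicInterval]:
    """Query intervals drawn exactly from the randomization null.

    Lengths follow the log-normal law; placement follows the engine's
    proportional-eligible-starts law, so this set IS a draw from the null
    (it may overlap itself, as the null allows).
    """
    rng = rng if rng is not None else _rng(spec, "queries")
    n = n if n is not None else spec.n_queries
    lengths = _query_lengths(spec, rng, n)
    frame = GlobalFrame(regions)
    lengths = np.minimum(lengths, int(frame.region_lengths.max()))
    randomizer = QueryRandomizer(lengths, frame)
    gstart, ridx = randomizer.draw_global(rng, 1)
    ivs = frame.lift(gstart[0], lengths, ridx[0])
    ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    return [
        dataclasses.replace(iv, name=f"sar_{i + 1:04d}") for i, iv in enumerate(ivs)
    ]


def generate_sar_like_set(
    spec: SyntheticSpec,
    regions: RegionSet,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    min_gap_bp: int = 2501,
    max_attempts: int = 10_000,
) -> list[GenomicInterval]:
    """A disjoint, gap-joined-looking stand-in for a deposited interval table.

    Same length law as :func:`generate_query_set`, but placements that come
    within ``min_gap_bp`` of an already-placed interval are redrawn, so the
    result has pairwise gaps >= ``min_gap_bp`` (i.e. it is a fixed point of
    the gap-joining rule) — the shape a post-processed attachment-site set
    has.  This is a synthetic stand-in, not real data.
    """
    rng = rng if rng is not None else _rng(spec, "sar_like")
    n = n if n is not None else spec.n_queries
    lengths = _query_lengths(spec, rng, n)
    frame = GlobalFrame(regions)
    lengths = np.minimum(lengths, int(frame.region_lengths.max()))
    # place longest first: large intervals are the hardest to fit
    order = np.argsort(-lengths)
    placed_s: list[int] = []
    placed_e: list[int] = []
    out_g: list[tuple[int, int, int]] = []  # (gstart, length, region)
    for i in order.tolist():
        L = int(lengths[i])
        randomizer = QueryRandomizer(np.array([L]), frame)
        for _ in range(max_attempts):
            gstart, ridx = randomizer.draw_global(rng, 1)
            s = int(gstart[0, 0])
            e = s + L
            ok = True
            for ps, pe in zip(placed_s, placed_e):
                if s - pe < min_gap_bp and ps - e < min_gap_bp:
                    ok = False
                    break
            if ok:
                placed_s.append(s)
                placed_e.append(e)
                out_g.append((s, L, int(ridx[0, 0])))
                break
        else:
            raise RuntimeError(
                f"could not place interval of {L} bp after {max_attempts} attempts"
            )
    gs = np.array([g for g, _, _ in out_g], dtype=np.int64)
    ls = np.array([l for _, l, _ in out_g], dtype=np.int64)
    rs = np.array([r for _, _, r in out_g], dtype=np.int64)
    ivs = frame.lift(gs, ls, rs)
    ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    return [
        dataclasses.replace(iv, name=f"sar_{i + 1:04d}") for i, iv in enumerate(ivs)
    ]


# ---------------------------------------------------------------------------
# Planted target tracks and their analytic oracle
# ---------------------------------------------------------------------------

def _overlap_start_ranges(
    query: list[GenomicInterval], regions: RegionSet, target_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per query: inclusive global range [lo, hi] of target start positions
    that overlap the query while staying inside its region, plus region idx."""
    assignment = assign_to_regions(query, regions)
    if assignment.n_assigned != len(query):
        raise ValueError("all query intervals must lie wholly within the regions")
    frame = GlobalFrame(regions)
    ridx = np.asarray(assignment.region_index, dtype=np.int64)
    ivs = assignment.assigned
    a = np.array([iv.start for iv in ivs], dtype=np.int64)
    b = np.array([iv.end for iv in ivs], dtype=np.int64)
    loc_a = a - frame.region_starts[ridx]
    loc_b = b - frame.region_starts[ridx]
    lo = np.maximum(loc_a - target_len + 1, 0)
    hi = np.minimum(loc_b - 1, frame.region_lengths[ridx] - target_len)
    if (hi < lo).any():
        raise ValueError("target length exceeds a region holding a query")
    return frame.offsets[ridx] + lo, frame.offsets[ridx] + hi, ridx


def generate_target_track(
    spec: SyntheticSpec,
    regions: RegionSet,
    query: list[GenomicInterval],
    rng: np.random.Generator | None = None,
    pi: float | None = None,
    n: int | None = None,
    length: int | None = None,
    name: str = "targets",
    mode: str = "count",
    distance_bp: int = 0,
) -> FeatureTrack:
    """Targets from the mixture law: forced-overlap with prob. pi, null else."""
    if rng is None:
        rng = np.random.default_rng(track_seed(spec.rng_seed, f"track:{name}"))
    pi = spec.colocation_prob if pi is None else pi
    n = n if n is not None else spec.n_targets
    length = length if length is not None else spec.target_length_bp
    frame = GlobalFrame(regions)
    lo, hi, _ = _overlap_start_ranges(query, regions, length)

    forced = rng.random(n) < pi
    gstarts = np.empty(n, dtype=np.int64)
    k = rng.integers(0, len(query), size=n)
    width = hi[k] - lo[k] + 1
    u = rng.random(n)
    forced_starts = lo[k] + np.minimum(
        np.floor(u * width).astype(np.int64), width - 1
    )
    randomizer = QueryRandomizer(np.full(n, length, dtype=np.int64), frame)
    null_starts, null_ridx = randomizer.draw_global(rng, 1)
    gstarts = np.where(forced, forced_starts, null_starts[0])
    # recover region index from the global offset
    ridx = np.searchsorted(frame.offsets, gstarts, side="right") - 1
    lengths = np.full(n, length, dtype=np.int64)
    ivs = frame.lift(gstarts, lengths, ridx)
    ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    ivs = [
        dataclasses.replace(iv, name=f"{name}_{i + 1:04d}")
        for i, iv in enumerate(ivs)
    ]
    return FeatureTrack(name, ivs, overlap_mode=mode, distance_bp=distance_bp)


def planted_count_truth(
    query: list[GenomicInterval],
    regions: RegionSet,
    n_targets: int,
    target_length: int,
    pi: float,
) -> dict:
    """Closed-form expectation/SD of the count-overlap statistic under the
    planted mixture, for the realized query set.

    Exact per-target miss probabilities (incidental overlaps of targets
    forced onto *other* queries included); the SD uses the independent-
    Bernoulli approximation across queries, which slightly over-states the
    spread (cross-query covariances are negative).
    """
    lo, hi, _ = _overlap_start_ranges(query, regions, target_length)
    w = (hi - lo + 1).astype(np.float64)
    frame = GlobalFrame(regions)
    elig = np.maximum(frame.region_lengths - target_length + 1, 0)
    W = float(elig.sum())
    n_q = len(query)
    inter = np.maximum(
        np.minimum(hi[:, None], hi[None, :])
        - np.maximum(lo[:, None], lo[None, :])
        + 1,
        0,
    ).astype(np.float64)
    # miss prob of one target w.r.t. query i
    forced_miss = (1.0 - inter / w[None, :]).mean(axis=1)  # avg over chosen k
    null_miss = 1.0 - w / W
    m = (1.0 - pi) * null_miss + pi * forced_miss
    p_hit = 1.0 - m**n_targets
    expected = float(p_hit.sum())
    sd = float(np.sqrt((p_hit * (1.0 - p_hit)).sum()))
    return {
        "pi": pi,
        "n_targets": n_targets,
        "target_length_bp": target_length,
        "n_queries": n_q,
        "expected_count": expected,
        "sd_count": sd,
    }


def expected_null_count(
    query: list[GenomicInterval],
    targets: FeatureTrack | list[GenomicInterval],
    regions: RegionSet,
) -> float:
    """Exact expected count-overlap of null-placed queries vs fixed targets.

    This is the population value the randomization's null mean estimates:
    for each query length, the fraction of eligible placements that touch
    the (region-clipped) target set, summed over queries.
    """
    if not isinstance(targets, FeatureTrack):
        targets = FeatureTrack("targets", list(targets))
    frame = GlobalFrame(regions)
    ts, te = frame.project_track(targets)
    t_ridx = np.searchsorted(frame.offsets, ts, side="right") - 1
    assignment = assign_to_regions(query, regions)
    lengths = np.array([iv.length for iv in assignment.assigned], dtype=np.int64)
    total = 0.0
    for L in lengths.tolist():
        elig = np.maximum(frame.region_lengths - L + 1, 0)
        W = float(elig.sum())
        # start positions hitting >= 1 target, per region, then unioned
        lo = np.maximum(ts - L + 1, frame.offsets[t_ridx])
        hi = np.minimum(te - 1, frame.offsets[t_ridx] + frame.region_lengths[t_ridx] - L)
        keep = hi >= lo
        hit = 0
        if keep.any():
            order = np.argsort(lo[keep])
            ls, hs = lo[keep][order], hi[keep][order]
            cur_lo, cur_hi = int(ls[0]), int(hs[0])
            for s, e in zip(ls[1:].tolist(), hs[1:].tolist()):
                if s > cur_hi + 1:
                    hit += cur_hi - cur_lo + 1
                    cur_lo, cur_hi = s, e
                else:
                    cur_hi = max(cur_hi, e)
            hit += cur_hi - cur_lo + 1
        total += hit / W
    return total


# ---------------------------------------------------------------------------
# Class tracks and genes
# ---------------------------------------------------------------------------

def generate_class_tracks(
    spec: SyntheticSpec,
    regions: RegionSet,
    rng: np.random.Generator | None = None,
    classes: tuple[str, ...] = ("early", "mid", "late"),
    segment_bp: int = 100_000,
    weights: tuple[float, ...] | None = None,
) -> list[FeatureTrack]:
    """Class tracks (e.g. replication timing) tiling the regions.

    Each region is cut into ~``segment_bp`` segments assigned to a class
    (probabilities ``weights``, uniform by default); the tracks partition
    the survey space exactly.
    """
    rng = rng if rng is not None else _rng(spec, "classes")
    if weights is None:
        weights = tuple(1.0 / len(classes) for _ in classes)
    elements: dict[str, list[GenomicInterval]] = {c: [] for c in classes}
    for region in regions:
        pos = region.start
        while pos < region.end:
            end = min(pos + segment_bp, region.end)
            cls = classes[int(rng.choice(len(classes), p=weights))]
            elements[cls].append(GenomicInterval(region.chrom, pos, end))
            pos = end
    return [
        FeatureTrack(c, elements[c], overlap_mode="bp") for c in classes
    ]


def generate_gene_track(
    spec: SyntheticSpec,
    regions: RegionSet,
    rng: np.random.Generator | None = None,
    n_genes: int = 300,
    median_bp: float = 20_000.0,
    sigma_log: float = 0.8,
    expressed_prob: float = 0.6,
) -> list[GeneModel]:
    """Stranded gene bodies placed by the null law with an expressed flag."""
    rng = rng if rng is not None else _rng(spec, "genes")
    lengths = np.round(
        rng.lognormal(mean=math.log(median_bp), sigma=sigma_log, size=n_genes)
    ).astype(np.int64)
    lengths = np.clip(lengths, 200, None)
    frame = GlobalFrame(regions)
    lengths = np.minimum(lengths, int(frame.region_lengths.max()))
    randomizer = QueryRandomizer(lengths, frame)
    gstart, ridx = randomizer.draw_global(rng, 1)
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    expressed = rng.random(n_genes) < expressed_prob
    ivs = frame.lift(gstart[0], lengths, ridx[0])
    genes = []
    order = sorted(range(n_genes), key=lambda i: (ivs[i].chrom, ivs[i].start))
    for rank, i in enumerate(order):
        body = dataclasses.replace(
            ivs[i],
            name=f"gene_{rank + 1:04d}",
            strand=str(strands[i]),
            flags={"expressed": bool(expressed[i])},
        )
        genes.append(GeneModel(body=body, expressed=bool(expressed[i])))
    return genes


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def generate_sequences(
    spec: SyntheticSpec,
    regions: RegionSet,
    query: list[GenomicInterval],
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Synthetic genome: independent bases, P(A or T) = ``at_query`` inside
    query intervals and ``at_background`` elsewhere inside regions; bases
    outside regions are N.  One record per chromosome, upper-case."""
    rng = rng if rng is not None else _rng(spec, "sequences")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    q_by_chrom: dict[str, list[GenomicInterval]] = {}
    for q in query:
        q_by_chrom.setdefault(q.chrom, []).append(q)
    out: dict[str, str] = {}
    for chrom in sorted(by_chrom):
        chrom_len = max(r.end for r in by_chrom[chrom])
        seq = np.full(chrom_len, ord("N"), dtype=np.uint8)
        for region in by_chrom[chrom]:
            p_at = np.full(region.length, spec.at_background)
            for q in q_by_chrom.get(chrom, []):
                s = max(q.start, region.start) - region.start
                e = min(q.end, region.end) - region.start
                if e > s:
                    p_at[s:e] = spec.at_query
            is_at = rng.random(region.length) < p_at
            second = rng.random(region.length) < 0.5
            bases = np.where(
                is_at,
                np.where(second, ord("A"), ord("T")),
                np.where(second, ord("C"), ord("G")),
            ).astype(np.uint8)
            seq[region.start : region.end] = bases
        out[chrom] = seq.tobytes().decode("ascii")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# qPCR panel
# ---------------------------------------------------------------------------

def generate_qpcr_panel(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    n_sites: int = 48,
    n_true: int = 46,
    n_negative: int = 16,
    true_enrichment: float | None = None,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic qPCR table: standards, scaffold/genomic Ct values, roles.

    ``n_true`` of the ``n_sites`` candidate sites carry a scaffold/genomic
    quantity ratio of ``true_enrichment``; the rest (and the negative
    regions and the ApoB-like negative control) have ratio 1.  Ct values
    follow the log-linear curve with Normal(0, ``qpcr_noise_sd``) noise.
    Returns (table, truth) where truth names the planted null sites.
    """
    rng = rng if rng is not None else _rng(spec, "qpcr")
    if not 0 <= n_true <= n_sites:
        raise ValueError("need 0 <= n_true <= n_sites")
    enr = spec.qpcr_true_enrichment if true_enrichment is None else true_enrichment
    null_idx = sorted(
        rng.choice(n_sites, size=n_sites - n_true, replace=False).tolist()
    )
    rows = []

    def _ct(quantity: float) -> float:
        return (
            spec.qpcr_intercept
            + spec.qpcr_slope * math.log10(quantity)
            + rng.normal(0.0, spec.qpcr_noise_sd)
        )

    def emit(site: str, role: str, ratio: float) -> None:
        for logq in range(5):
            rows.append(
                {
                    "site": site, "role": role, "fraction": "standard",
                    "replicate": logq + 1, "ct": round(_ct(10.0**logq), 4),
                    "log10_quantity": float(logq),
                }
            )
        genomic_q = 100.0
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "site": site, "role": role, "fraction": "genomic",
                    "replicate": rep, "ct": round(_ct(genomic_q), 4),
                    "log10_quantity": float("nan"),
                }
            )
            rows.append(
                {
                    "site": site, "role": role, "fraction": "scaffold",
                    "replicate": rep, "ct": round(_ct(genomic_q * ratio), 4),
                    "log10_quantity": float("nan"),
                }
            )

    for i in range(n_sites):
        emit(f"site_{i + 1:02d}", "candidate", 1.0 if i in null_idx else enr)
    for i in range(n_negative):
        emit(f"neg_{i + 1:02d}", "negative", 1.0)
    emit("ApoB_pos", "control", enr * 2.0)
    emit("ApoB_neg", "control", 1.0)
    truth = {
        "null_sites": [f"site_{i + 1:02d}" for i in null_idx],
        "true_enrichment": enr,
        "n_sites": n_sites,
        "n_true": n_true,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    regions: RegionSet
    sars: list[GenomicInterval]
    tracks: list[FeatureTrack]
    class_tracks: list[FeatureTrack]
    genes: list[GeneModel]
    sequences: dict[str, str]
    qpcr: pd.DataFrame
    truth: dict = field(default_factory=dict)


_DEFAULT_TRACKS = (
    # (name, pi, length_bp, mode)
    ("planted_tf", None, 300, "count"),
    ("open_chromatin", 0.3, 800, "count"),
    ("independent", 0.0, 500, "count"),
    ("repeat_like", 0.2, 300, "containment"),
)


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """The full default synthetic dataset with its analytic ground truth."""
    spec = spec if spec is not None else SyntheticSpec()
    regions = generate_regions(spec)
    sars = generate_sar_like_set(spec, regions)
    tracks = []
    truth: dict = {"tracks": {}}
    for name, pi, length, mode in _DEFAULT_TRACKS:
        pi_eff = spec.colocation_prob if pi is None else pi
        track = generate_target_track(
            spec, regions, sars, pi=pi_eff, length=length, name=name, mode=mode
        )
        tracks.append(track)
        entry = planted_count_truth(
            sars, regions, spec.n_targets, length, pi_eff
        )
        entry["expected_null_count"] = expected_null_count(sars, track, regions)
        if entry["expected_null_count"] > 0:
            entry["expected_enrichment_pct"] = (
                100.0
                * (entry["expected_count"] - entry["expected_null_count"])
                / entry["expected_null_count"]
            )
        truth["tracks"][name] = entry
    class_tracks = generate_class_tracks(spec, regions)
    genes = generate_gene_track(spec, regions)
    sequences = generate_sequences(spec, regions, sars)
    qpcr, qpcr_truth = generate_qpcr_panel(spec)
    truth["qpcr"] = qpcr_truth
    truth["at"] = {
        "at_query_pct": 100.0 * spec.at_query,
        "at_background_pct": 100.0 * spec.at_background,
    }
    return SyntheticDataset(
        spec=spec,
        regions=regions,
        sars=sars,
        tracks=tracks,
        class_tracks=class_tracks,
        genes=genes,
        sequences=sequences,
        qpcr=qpcr,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["regions"] = outdir / "regions.bed"
    write_bed(ds.regions.regions, paths["regions"])
    paths["sars"] = outdir / "sars.bed"
    write_bed(ds.sars, paths["sars"])
    for track in ds.tracks:
        p = outdir / f"track_{track.track_name}.bed"
        write_bed(track.elements, p)
        paths[f"track_{track.track_name}"] = p
    for track in ds.class_tracks:
        p = outdir / f"class_{track.track_name}.bed"
        write_bed(track.elements, p)
        paths[f"class_{track.track_name}"] = p
    paths["genes"] = outdir / "genes.ext.bed"
    write_bed([g.body for g in ds.genes], paths["genes"])
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(ds.sequences, paths["fasta"])
    paths["qpcr"] = outdir / "qpcr.csv"
    ds.qpcr.to_csv(paths["qpcr"], index=False)
    paths["truth"] = outdir / "truth.json"
    with paths["truth"].open("w") as fh:
        json.dump(ds.truth, fh, indent=2)
        fh.write("\n")
    return paths
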