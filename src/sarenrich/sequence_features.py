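"""AT-content analysis against the randomization null.

S/MAR sequences are classically AT-rich.  This module measures %A+T per
query interval (case-insensitive; IUPAC ambiguity codes are excluded from
numerator and denominator by default) and compares the MEDIAN across
intervals with the same statistic on randomized interval sets produced by
the region-constrained placement law of :mod:`sarenrich.enrichment_engine`
— one median per randomization, with the add-one empirical P.

Sequence sources can be a ``pyfaidx.Fasta``, a plain ``dict`` of
chromosome name -> sequence string, or anything indexable as
``source[chrom][start:end]``.  For the randomization loop the sequence
under each survey region is converted once into cumulative A/T and
informative-base counts, making each interval lookup O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import GenomicInterval, RegionSet, assign_to_regions
from .enrichment_engine import GlobalFrame, QueryRandomizer, empirical_p

_AT = frozenset(b"ATat")
_INFORMATIVE = frozenset(b"ACGTacgt")


@dataclass
class AtContentResult:
    observed_median_at_pct: float
    observed_mean_at_pct: float
    null_median_at_pcts: np.ndarray = field(repr=False)
    null_median_of_medians: float = float("nan")
    p_enrich: float = float("nan")
    p_deplete: float = float("nan")
    n_randomizations: int = 0
    per_interval_at: np.ndarray = field(repr=False, default=None)


def _fetch(source, chrom: str, start: int, end: int) -> str:
    seq = source[chrom][start:end]
    return str(seq)


def at_content(interval: GenomicInterval, sequence_source) -> float:
    """%A+T of one interval: 100·(#A+#T)/(#A+#C+#G+#T), case-insensitive.

    Ambiguous bases (N etc.) are excluded from both numerator and
    denominator; an interval with no informative base returns NaN.
    """
    seq = _fetch(sequence_source, interval.chrom, interval.start, interval.end)
    if len(seq) < interval.length:
        raise ValueError(
            f"sequence for {interval.chrom} ends before {interval.end}"
        )
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    at = np.isin(arr, np.frombuffer(b"AT", dtype=np.uint8)).sum()
    informative = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)).sum()
    if informative == 0:
        return float("nan")
    return 100.0 * float(at) / float(informative)


class _RegionAtIndex:
    """Per-region cumulative AT / informative counts on the linearized axis."""

    def __init__(
        self,
        regions: RegionSet,
        source,
        include_ambiguous: bool = False,
    ):
        self.concat_offsets = np.zeros(len(regions), dtype=np.int64)
        pos = 0
        at_parts, inf_parts = [], []
        for i, region in enumerate(regions):
            self.concat_offsets[i] = pos
            seq = _fetch(source, region.chrom, region.start, region.end).upper()
            if len(seq) < region.length:
                raise ValueError(
                    f"sequence for {region.chrom} ends before {region.end}"
                )
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_at = np.isin(arr, np.frombuffer(b"AT", dtype=np.uint8))
            if include_ambiguous:
                is_inf = np.ones(len(arr), dtype=bool)
            else:
                is_inf = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
            at_parts.append(is_at)
            inf_parts.append(is_inf)
            pos += region.length
        # int32 cumulative counts: fine up to ~2.1 Gb of surveyed sequence
        self.cum_at = np.concatenate(
            [[0], np.cumsum(np.concatenate(at_parts), dtype=np.int32)]
        )
        self.cum_inf = np.concatenate(
            [[0], np.cumsum(np.concatenate(inf_parts), dtype=np.int32)]
        )

    def pct(
        self, ridx: np.ndarray, local_start: np.ndarray, lengths: np.ndarray
    ) -> np.ndarray:
        lo = self.concat_offsets[ridx] + local_start
        hi = lo + lengths
        at = self.cum_at[hi] - self.cum_at[lo]
        inf = self.cum_inf[hi] - self.cum_inf[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(inf > 0, 100.0 * at / inf, np.nan)


def at_enrichment_test(
    query: list[GenomicInterval],
    regions: RegionSet,
    sequence_source,
    n_randomizations: int = 9999,
    rng_seed: int | np.random.Generator | np.random.SeedSequence = 0,
    include_ambiguous: bool = False,
    keep_region: bool = False,
    chunk_size: int = 512,
) -> AtContentResult:
    """Median AT% of the query set vs the randomization null.

    Observed statistic: median over intervals of per-interval AT%.  Each of
    the ``n_randomizations`` randomized sets (same placement law as the
    enrichment engine, shared seeding contract) contributes one null
    median; ``p_enrich`` applies the add-one rule to {null >= observed}.
    """
    rng = np.random.default_rng(rng_seed)
    assignment = assign_to_regions(query, regions)
    used = assignment.assigned
    if not used:
        raise ValueError("no query interval lies wholly within the regions")
    frame = GlobalFrame(regions)
    index = _RegionAtIndex(regions, sequence_source, include_ambiguous)

    ridx_obs = np.asarray(assignment.region_index, dtype=np.int64)
    starts = np.array([iv.start for iv in used], dtype=np.int64)
    lengths = np.array([iv.length for iv in used], dtype=np.int64)
    local_obs = starts - frame.region_starts[ridx_obs]
    per_interval = index.pct(ridx_obs, local_obs, lengths)
    observed_median = float(np.nanmedian(per_interval))
    observed_mean = float(np.nanmean(per_interval))

    randomizer = QueryRandomizer(
        lengths, frame,
        keep_region=keep_region,
        source_region=ridx_obs if keep_region else None,
    )
    null = np.empty(n_randomizations, dtype=np.float64)
    done = 0
    while done < n_randomizations:
        d = min(chunk_size, n_randomizations - done)
        gstart, ridx = randomizer.draw_global(rng, d)
        local = gstart - frame.offsets[ridx]
        pct = index.pct(ridx.ravel(), local.ravel(), np.tile(lengths, d))
        null[done : done + d] = np.nanmedian(pct.reshape(d, -1), axis=1)
        done += d
    p_enrich, p_deplete = empirical_p(null, observed_median)
    return AtContentResult(
        observed_median_at_pct=observed_median,
        observed_mean_at_pct=observed_mean,
        null_median_at_pcts=null,
        null_median_of_medians=float(np.median(null)),
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        n_randomizations=n_randomizations,
        per_interval_at=per_interval,
    )
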