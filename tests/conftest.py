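"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive O(n·m) / O(n^2) scans and
position-set arithmetic so they share no code path with the vectorized
implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import sarenrich as sr

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def fast_spec() -> sr.SyntheticSpec:
    """A scaled-down study: 8 regions (~2 Mb), 40 query intervals."""
    return sr.SyntheticSpec(
        n_regions=8,
        n_minimal_regions=4,
        region_length_range=(200_000, 400_000),
        n_queries=40,
        n_targets=80,
        rng_seed=3,
    )


@pytest.fixture
def fast_regions(fast_spec) -> sr.RegionSet:
    return sr.generate_regions(fast_spec)


@pytest.fixture
def fast_sars(fast_spec, fast_regions) -> list[sr.GenomicInterval]:
    return sr.generate_sar_like_set(fast_spec, fast_regions)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def oracle_merge(intervals: list[sr.GenomicInterval], gap: int) -> list[tuple]:
    """Transitive-closure union by repeated O(n^2) pairwise joining."""
    spans = [[iv.chrom, iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                if a[0] != b[0]:
                    continue
                g = max(a[1], b[1]) - min(a[2], b[2])
                if g < gap:  # overlap gives negative g
                    spans[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    del spans[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e) for c, s, e in spans)


def _overlaps(qs, qe, ts, te) -> bool:
    return ts < qe and qs < te


def _gap(qs, qe, ts, te) -> int:
    if _overlaps(qs, qe, ts, te):
        return 0
    return ts - qe if ts >= qe else qs - te


def oracle_overlap(query, targets, mode: str, distance_bp: int = 0) -> float:
    """All-pairs scan over (query, target) interval pairs."""
    total = 0
    for q in query:
        same = [t for t in targets if t.chrom == q.chrom]
        if mode == "count":
            total += any(_overlaps(q.start, q.end, t.start, t.end) for t in same)
        elif mode == "within_distance":
            if distance_bp == 0:
                total += any(_overlaps(q.start, q.end, t.start, t.end) for t in same)
            else:
                total += any(
                    _gap(q.start, q.end, t.start, t.end) <= distance_bp for t in same
                )
        elif mode == "containment":
            total += any(q.start <= t.start and t.end <= q.end for t in same)
        elif mode == "bp":
            covered: set[int] = set()
            for t in same:
                covered |= set(range(max(q.start, t.start), min(q.end, t.end)))
            total += len(covered)
        else:
            raise ValueError(mode)
    return float(total)


def random_instance(rng: np.random.Generator, n: int, m: int, span: int = 400):
    """A random query/target pair on two small chromosomes."""
    def draw(k):
        out = []
        for _ in range(k):
            chrom = "chrA" if rng.random() < 0.7 else "chrB"
            s = int(rng.integers(0, span))
            e = s + int(rng.integers(1, 30))
            out.append(sr.GenomicInterval(chrom, s, e))
        return out

    return draw(n), draw(m)
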