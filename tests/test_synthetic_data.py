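"""Determinism, placement laws and planted structure of the generators."""

import dataclasses
import math

import numpy as np
import pytest

import sarenrich as sr


# -- regions ------------------------------------------------------------------

def test_regions_deterministic_and_disjoint(fast_spec):
    a = sr.generate_regions(fast_spec)
    b = sr.generate_regions(fast_spec)
    assert [(r.chrom, r.start, r.end) for r in a] == [
        (r.chrom, r.start, r.end) for r in b
    ]
    lo, hi = fast_spec.region_length_range
    assert all(lo <= r.length <= hi for r in a)
    n_min = sum(1 for r in a if r.length == lo)
    assert n_min >= fast_spec.n_minimal_regions


def test_default_region_budget_matches_survey_scale():
    regions = sr.generate_regions(sr.SyntheticSpec())
    assert len(regions) == 44
    assert 22e6 <= regions.total_bp <= 88e6


def test_regions_disjoint_across_many_specs():
    for seed in range(20):
        spec = sr.SyntheticSpec(
            n_regions=6, n_minimal_regions=2,
            region_length_range=(50_000, 120_000), rng_seed=seed,
        )
        regions = sr.generate_regions(spec)  # RegionSet ctor enforces disjoint
        assert len(regions) == 6


# -- queries ------------------------------------------------------------------

def test_query_length_law_median_and_floor():
    spec = sr.SyntheticSpec(rng_seed=1)
    rng = np.random.default_rng(0)
    regions = sr.generate_regions(spec)
    q = sr.generate_query_set(spec, regions, rng=rng, n=10_000)
    lengths = np.array([iv.length for iv in q])
    assert lengths.min() >= spec.query_min_bp
    # median of 10k log-normal draws: 3 SEs around the law median
    se_log = 1.2533 * spec.query_sigma_log / math.sqrt(len(lengths))
    assert abs(math.log(np.median(lengths)) - math.log(spec.query_median_bp)) < 3 * se_log


def test_queries_confined_and_reproducible(fast_spec, fast_regions):
    a = sr.generate_query_set(fast_spec, fast_regions)
    b = sr.generate_query_set(fast_spec, fast_regions)
    assert a == b
    assert all(fast_regions.locate(iv) is not None for iv in a)


def test_sar_like_set_respects_merge_gap(fast_spec, fast_regions):
    sars = sr.generate_sar_like_set(fast_spec, fast_regions, min_gap_bp=2501)
    assert len(sars) == fast_spec.n_queries
    assert sr.merge_by_gap(sars, 2501) == sars  # fixed point of the join rule
    by_chrom: dict[str, list] = {}
    for s in sars:
        by_chrom.setdefault(s.chrom, []).append(s)
    for group in by_chrom.values():
        group.sort(key=lambda x: x.start)
        assert all(b.start - a.end >= 2501 for a, b in zip(group, group[1:]))


# -- targets and the analytic oracle -----------------------------------------

def test_pi_one_targets_all_overlap_a_query(fast_spec, fast_regions, fast_sars):
    track = sr.generate_target_track(
        fast_spec, fast_regions, fast_sars, pi=1.0, length=200
    )
    stat = sr.OverlapStatistic("count")
    # every target overlaps some query (roles swapped for the check)
    assert sr.overlap_statistic(track.elements, fast_sars, stat) == len(track.elements)


def test_pi_zero_targets_follow_null_law(fast_spec, fast_regions, fast_sars):
    track = sr.generate_target_track(fast_spec, fast_regions, fast_sars, pi=0.0)
    truth = sr.planted_count_truth(
        fast_sars, fast_regions, fast_spec.n_targets, fast_spec.target_length_bp, 0.0
    )
    obs = sr.overlap_statistic(
        fast_sars, track, sr.OverlapStatistic("count")
    )
    assert abs(obs - truth["expected_count"]) < 4 * truth["sd_count"] + 1


def test_planted_truth_pi_one_short_targets_counts_distinct_hits(fast_regions, fast_spec):
    """pi=1 with targets shorter than queries: E[count] = E[#distinct queries hit]."""
    sars = sr.generate_sar_like_set(fast_spec, fast_regions)
    n_t = 60
    truth = sr.planted_count_truth(sars, fast_regions, n_t, 50, 1.0)
    n_q = len(sars)
    # forced choice is uniform over queries and a 50 bp target rarely strays:
    # distinct-count expectation n(1-(1-1/n)^m) is an upper-bound reference
    distinct = n_q * (1 - (1 - 1 / n_q) ** n_t)
    assert truth["expected_count"] == pytest.approx(distinct, rel=0.05)
    track = sr.generate_target_track(fast_spec, fast_regions, sars, pi=1.0, n=n_t, length=50)
    obs = sr.overlap_statistic(sars, track, sr.OverlapStatistic("count"))
    assert abs(obs - truth["expected_count"]) < 4 * truth["sd_count"] + 1


def test_expected_null_count_matches_monte_carlo(fast_spec, fast_regions, fast_sars):
    track = sr.generate_target_track(fast_spec, fast_regions, fast_sars, pi=0.4)
    exact = sr.expected_null_count(fast_sars, track, fast_regions)
    rng = np.random.default_rng(2)
    stat = sr.OverlapStatistic("count")
    draws = [
        sr.overlap_statistic(
            sr.randomize_query(fast_sars, fast_regions, rng), track, stat
        )
        for _ in range(400)
    ]
    mc = float(np.mean(draws))
    se = float(np.std(draws, ddof=1) / np.sqrt(len(draws)))
    assert abs(mc - exact) < 4 * se + 0.05


# -- sequences ----------------------------------------------------------------

def test_sequence_lengths_and_at_laws(fast_spec, fast_regions, fast_sars):
    seqs = sr.generate_sequences(fast_spec, fast_regions, fast_sars)
    for region in fast_regions:
        assert len(seqs[region.chrom]) >= region.end
        body = seqs[region.chrom][region.start : region.end]
        assert "N" not in body
    # background AT near 50%
    r0 = fast_regions[0]
    body = seqs[r0.chrom][r0.start : r0.end]
    at = (body.count("A") + body.count("T")) / len(body)
    assert at == pytest.approx(
        fast_spec.at_background, abs=0.02
    ) or at > fast_spec.at_background  # queries inside raise it slightly
    # planted islands near at_query
    q = fast_sars[0]
    island = seqs[q.chrom][q.start : q.end]
    at_q = (island.count("A") + island.count("T")) / len(island)
    sd = math.sqrt(0.65 * 0.35 / len(island))
    assert abs(at_q - fast_spec.at_query) < 4 * sd


def test_fasta_round_trip(tmp_path, fast_spec):
    regions = sr.RegionSet([sr.GenomicInterval("chrZ", 100, 5100)])
    seqs = sr.generate_sequences(fast_spec, regions, [])
    p = tmp_path / "g.fa"
    sr.write_fasta(seqs, p)
    import pyfaidx

    fa = pyfaidx.Fasta(str(p))
    assert str(fa["chrZ"][:]) == seqs["chrZ"]


# -- whole dataset ------------------------------------------------------------

def test_dataset_bundle_is_deterministic_and_complete(tmp_path):
    spec = sr.SyntheticSpec(
        n_regions=5, n_minimal_regions=2, region_length_range=(80_000, 150_000),
        n_queries=25, n_targets=50, rng_seed=9,
    )
    ds1 = sr.generate_dataset(spec)
    ds2 = sr.generate_dataset(spec)
    assert ds1.sars == ds2.sars
    assert ds1.qpcr.equals(ds2.qpcr)
    assert {t.track_name for t in ds1.tracks} == {
        "planted_tf", "open_chromatin", "independent", "repeat_like"
    }
    paths = sr.write_dataset(ds1, tmp_path / "d1")
    paths2 = sr.write_dataset(ds2, tmp_path / "d2")
    for key in paths:
        assert paths[key].read_bytes() == paths2[key].read_bytes(), key


def test_spec_validation():
    with pytest.raises(ValueError):
        sr.SyntheticSpec(colocation_prob=1.5)
    with pytest.raises(ValueError):
        sr.SyntheticSpec(at_query=0.0)
    with pytest.raises(ValueError):
        sr.SyntheticSpec(n_minimal_regions=99)
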