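"""Overlap statistics, the randomization null and the empirical test."""

import numpy as np
import pytest

import sarenrich as sr
from conftest import oracle_overlap, random_instance


def iv(s, e, chrom="chr1"):
    return sr.GenomicInterval(chrom, s, e)


# -- overlap_statistic --------------------------------------------------------

def test_count_mode_counts_each_query_once():
    query = [iv(0, 10), iv(20, 30)]
    targets = [iv(5, 6), iv(7, 8)]
    assert sr.overlap_statistic(query, targets, sr.OverlapStatistic("count")) == 1


def test_within_distance_threshold_semantics():
    query, target = [iv(0, 10)], [iv(14, 20)]
    within = sr.OverlapStatistic("within_distance", 5000)
    assert sr.overlap_statistic(query, target, within) == 1
    tight = sr.OverlapStatistic("within_distance", 3)
    assert sr.overlap_statistic(query, target, tight) == 0  # nearest gap is 4
    exact = sr.OverlapStatistic("within_distance", 4)
    assert sr.overlap_statistic(query, target, exact) == 1


def test_containment_and_bp_modes():
    query = [iv(0, 100), iv(200, 210)]
    targets = [iv(10, 20), iv(205, 250)]
    contain = sr.OverlapStatistic("containment")
    assert sr.overlap_statistic(query, targets, contain) == 1
    bp = sr.OverlapStatistic("bp")
    assert sr.overlap_statistic(query, targets, bp) == 10 + 5


def test_bp_mode_does_not_double_count_overlapping_targets():
    query = [iv(0, 100)]
    targets = [iv(10, 50), iv(30, 70)]
    assert sr.overlap_statistic(query, targets, sr.OverlapStatistic("bp")) == 60


def test_unknown_mode_rejected():
    with pytest.raises(ValueError):
        sr.OverlapStatistic("jaccard")


@pytest.mark.parametrize("mode,dist", [
    ("count", 0), ("within_distance", 7), ("containment", 0), ("bp", 0),
])
def test_overlap_statistic_matches_all_pairs_oracle(mode, dist):
    rng = np.random.default_rng(17)
    stat = sr.OverlapStatistic(mode, dist)
    for _ in range(200):
        n, m = int(rng.integers(0, 50)) + 1, int(rng.integers(0, 50))
        query, targets = random_instance(rng, n, m)
        assert sr.overlap_statistic(query, targets, stat) == oracle_overlap(
            query, targets, mode, dist
        ), (query, targets)


# -- randomize_query ----------------------------------------------------------

def test_randomize_uniform_start_law():
    """Single length-10 interval in [0,100): starts uniform on {0..90}."""
    regions = sr.RegionSet([iv(0, 100)])
    query = [iv(40, 50)]
    rng = np.random.default_rng(5)
    counts = np.zeros(91, dtype=int)
    n_draws = 10_000
    for _ in range(n_draws):
        (out,) = sr.randomize_query(query, regions, rng)
        counts[out.start] += 1
    p = 1 / 91
    sd = np.sqrt(n_draws * p * (1 - p))
    assert counts.sum() == n_draws
    assert (np.abs(counts - n_draws * p) < 4 * sd + 1).all()


def test_randomize_full_region_interval_is_deterministic():
    regions = sr.RegionSet([iv(0, 100)])
    (out,) = sr.randomize_query([iv(0, 100)], regions, np.random.default_rng(0))
    assert (out.start, out.end) == (0, 100)


def test_randomize_region_choice_proportional_to_eligible_starts():
    regions = sr.RegionSet([iv(0, 1000), iv(0, 3000, chrom="chr2")])
    query = [iv(10, 11)]
    rng = np.random.default_rng(9)
    hits2 = 0
    n_draws = 8000
    for _ in range(n_draws):
        (out,) = sr.randomize_query(query, regions, rng)
        hits2 += out.chrom == "chr2"
    p = 3000 / 4000
    sd = np.sqrt(n_draws * p * (1 - p))
    assert abs(hits2 - n_draws * p) < 4 * sd


def test_randomize_preserves_lengths_and_confinement(fast_regions, fast_sars):
    rng = np.random.default_rng(1)
    out = sr.randomize_query(fast_sars, fast_regions, rng)
    assert sorted(o.length for o in out) == sorted(s.length for s in fast_sars)
    assert all(fast_regions.locate(o) is not None for o in out)


def test_randomize_keep_region_confines_to_source(fast_regions, fast_sars):
    rng = np.random.default_rng(2)
    out = sr.randomize_query(fast_sars, fast_regions, rng, keep_region=True)
    src = sr.assign_to_regions(fast_sars, fast_regions)
    dst = sr.assign_to_regions(out, fast_regions)
    assert [len(v) for v in src.by_region.values()] == [
        len(v) for v in dst.by_region.values()
    ]


def test_randomizer_oversized_interval_errors():
    from sarenrich.enrichment_engine import GlobalFrame, QueryRandomizer

    regions = sr.RegionSet([iv(0, 100), iv(0, 50, chrom="chr2")])
    with pytest.raises(ValueError, match="does not fit"):
        QueryRandomizer(np.array([200]), GlobalFrame(regions))


# -- empirical P and enrichment_test -----------------------------------------

def test_empirical_p_add_one_extremes():
    null = np.arange(9999, dtype=float)
    p_enrich, p_deplete = sr.empirical_p(null, 10_000.0)
    assert p_enrich == pytest.approx(1 / 10_000)
    assert p_deplete == 1.0


def test_self_overlap_saturates_p_floor(fast_regions, fast_sars):
    track = sr.FeatureTrack("self", list(fast_sars))
    res = sr.enrichment_test(
        fast_sars, track, fast_regions, n_randomizations=199, rng_seed=4
    )
    assert res.observed == len(fast_sars)
    assert res.p_enrich <= 0.05
    assert 1 / 200 <= res.p_enrich <= 1.0 and 1 / 200 <= res.p_deplete <= 1.0


def test_enrichment_same_seed_bit_reproducible(fast_regions, fast_sars, fast_spec):
    track = sr.generate_target_track(fast_spec, fast_regions, fast_sars, pi=0.3)
    a = sr.enrichment_test(fast_sars, track, fast_regions, n_randomizations=99, rng_seed=7)
    b = sr.enrichment_test(fast_sars, track, fast_regions, n_randomizations=99, rng_seed=7)
    assert a.observed == b.observed
    assert np.array_equal(a.null_values, b.null_values)
    c = sr.enrichment_test(fast_sars, track, fast_regions, n_randomizations=99, rng_seed=8)
    assert not np.array_equal(a.null_values, c.null_values)


def test_null_mean_matches_exact_expectation(fast_regions, fast_sars, fast_spec):
    """The MC null mean estimates the closed-form placement expectation."""
    track = sr.generate_target_track(fast_spec, fast_regions, fast_sars, pi=0.0)
    res = sr.enrichment_test(
        fast_sars, track, fast_regions, n_randomizations=999, rng_seed=13
    )
    exact = sr.expected_null_count(fast_sars, track, fast_regions)
    mc_sd = res.null_sd / np.sqrt(res.n_randomizations)
    assert abs(res.null_mean - exact) < 4 * mc_sd + 0.05


def test_zero_null_mean_flags_enrichment_undefined():
    regions = sr.RegionSet([iv(0, 10_000)])
    query = [iv(0, 10_000)]  # only one placement: always overlaps itself
    far_track = sr.FeatureTrack("none", [])
    res = sr.enrichment_test(query, far_track, regions, n_randomizations=19, rng_seed=1)
    assert res.observed == 0 and res.null_mean == 0
    assert not res.enrichment_defined
    assert np.isnan(res.enrichment_pct)
    assert 0 < res.p_enrich <= 1


# -- reciprocal and class tests ----------------------------------------------

def test_reciprocal_randomizes_the_target_set(fast_regions, fast_sars, fast_spec):
    track = sr.generate_target_track(fast_spec, fast_regions, fast_sars, pi=0.6)
    fwd = sr.enrichment_test(fast_sars, track, fast_regions, n_randomizations=99, rng_seed=3)
    rev = sr.reciprocal_test(fast_sars, track, fast_regions, n_randomizations=99, rng_seed=3)
    assert rev.n_query_used == len(track.elements)
    assert rev.track_name.endswith("|reciprocal")
    # both directions should detect the planted association
    assert fwd.p_enrich <= 0.05 and rev.p_enrich <= 0.05


def test_reciprocal_direction_changes_the_count_statistic(fast_regions):
    big = [sr.GenomicInterval(fast_regions[0].chrom,
                              fast_regions[0].start,
                              fast_regions[0].start + 150_000)]
    targets = [
        sr.GenomicInterval(big[0].chrom, big[0].start + 1000 * i, big[0].start + 1000 * i + 100)
        for i in range(20)
    ]
    track = sr.FeatureTrack("points", targets)
    fwd = sr.enrichment_test(big, track, fast_regions, n_randomizations=19, rng_seed=0)
    rev = sr.reciprocal_test(big, track, fast_regions, n_randomizations=19, rng_seed=0)
    assert fwd.observed == 1  # one query interval hit
    assert rev.observed == 20  # every target hits the query


def test_class_partition_conserves_bp_on_every_draw(fast_regions, fast_sars, fast_spec):
    classes = sr.generate_class_tracks(fast_spec, fast_regions)
    results = sr.class_overlap_test(
        fast_sars, classes, fast_regions, n_randomizations=49, rng_seed=21
    )
    total_query_bp = sum(s.length for s in fast_sars)
    assert sum(r.observed for r in results) == total_query_bp
    null_sum = np.sum([r.null_values for r in results], axis=0)
    assert np.allclose(null_sum, total_query_bp)


def test_query_inside_one_class_signs_enrichment(fast_regions):
    region = fast_regions[0]
    half = (region.start + region.end) // 2
    early = sr.FeatureTrack("early", [sr.GenomicInterval(region.chrom, region.start, half)],
                            overlap_mode="bp")
    late_els = [sr.GenomicInterval(region.chrom, half, region.end)] + [
        sr.GenomicInterval(r.chrom, r.start, r.end) for r in list(fast_regions)[1:]
    ]
    late = sr.FeatureTrack("late", late_els, overlap_mode="bp")
    query = [sr.GenomicInterval(region.chrom, region.start + 10, region.start + 5010)]
    res_early, res_late = sr.class_overlap_test(
        query, [early, late], fast_regions, n_randomizations=99, rng_seed=2
    )
    assert res_early.enrichment_pct > 0
    assert res_late.enrichment_pct < 0


def test_track_seed_is_stable_and_track_specific():
    a = sr.track_seed(42, "pol2")
    b = sr.track_seed(42, "pol2")
    c = sr.track_seed(42, "ctcf")
    assert np.random.default_rng(a).integers(1 << 30) == np.random.default_rng(b).integers(1 << 30)
    assert np.random.default_rng(a).integers(1 << 30) != np.random.default_rng(c).integers(1 << 30)
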