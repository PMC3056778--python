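# Methods

## The analysis model

The pipeline treats a scaffold-attachment survey as three fixed objects:
a **RegionSet** of pairwise-disjoint survey regions (the only genomic space
any statistic ever sees), a **query set** of half-open intervals wholly
contained in those regions, and one or more **target tracks**.  Every
question — "are attachment sites near genes / polymerase sites / AT-rich
sequence?" — is answered by comparing an observed overlap statistic with an
empirical null obtained by re-placing the query intervals inside the
regions.

Assumptions of the null: the number of query intervals and their exact
lengths are ancillary (conditioned on); placements are exchangeable across
regions with probability proportional to the count of eligible start
positions, `region_length − interval_length + 1`; randomized intervals may
overlap one another.  Nothing else (GC content, gap structure, clustering)
is preserved — the null is deliberately the simplest exchangeable model
consistent with confinement to the survey regions.  A `keep_region` option
confines each interval to its source region for sensitivity analysis.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `merge_gap_bp` | 2501 | bp | calls "< 2501 bp apart" are joined: gaps ≤ 2500 bp merge, a gap of exactly 2501 does not (literal reading of the rule) |
| `n_randomizations` | 9999 | — | P floor 1/(N+1) = 0.0001 with the add-one estimator |
| `proximity_bp` | 5000 | bp | "within 5 kb" proximity calls; endpoint-inclusive at d > 0 |
| `z_threshold` | 8 | sd | a qPCR site validates at ≥ 8 negative-control standard deviations |
| `upstream_bp` | 5000 | bp | promoter-proxy window upstream of the TSS in the genic breakdown |

## Numerical and convention choices

- **Coordinates** are 0-based half-open everywhere.  BED is native;
  spreadsheet-style tables are 1-based inclusive and converted on read
  (configurable; the conversion is an involution with its inverse).
- **Straddling queries are excluded, not clipped**: the null places whole
  intervals inside regions, so clipping would put observed and null
  statistics on different supports.  Target tracks, by contrast, are
  clipped — their bp inside the survey space is what the statistic sees.
- **`within_distance` semantics**: d = 0 reduces exactly to direct overlap
  (a book-ended target does not count); at d > 0 a separation of exactly
  d bp counts.  This keeps the d = 0 statistic identical to `count`.
- **Empirical P** uses the add-one estimator with inclusive tails (ties
  count as significant in both directions); it can never return 0 and its
  floor matches the 0.0001 convention at N = 9999.  No multiple-testing
  correction is applied; reports carry the number of tests run.
- **Enrichment %** is defined against the null mean; the null median is
  also reported (the AT analysis compares medians).  When the null mean is
  0 the percentage is flagged undefined (NaN) while the P values remain
  valid.
- **Median** of an even count is the mean of the two central order
  statistics.
- **Inter-site distance** is the gap `start(next) − end(prev)` (loop DNA
  between attachment points); midpoint-to-midpoint is available behind a
  flag.  Regions with no interval contribute their whole length to the
  excluded fraction; single-interval regions contribute both flanks.
- **Signed TSS/TES distances**: 0 on overlap; otherwise the gap bp, signed
  positive when the point lies downstream of the query in the point's
  strand orientation (a `genomic` orientation flag signs by left/right
  instead).  Equal-distance ties resolve downstream.
- **AT content** excludes ambiguity codes from numerator and denominator
  (an option counts them as non-AT); an all-N interval is NaN and drops
  out of medians.
- **qPCR**: sample (n−1) standard deviation; the FDR denominator is the
  number of *validated* sites (2/46 → 4.3%), with the tested-denominator
  variant behind a flag; sites may enter as Ct values (per-site standard
  curve, pooled-curve fallback) or as quantities.
- **Seeding**: one master seed; per-track child streams derive from a
  stable SHA-256 hash of the track name, so adding a track never changes
  another track's result.  Same seed ⇒ bit-identical output.  The uniform
  placement draw uses a float64 cell offset (bias < 2⁻⁵³ per draw),
  clamped so a draw can never escape its probability cell.
- **Engine internals**: regions (or chromosomes) are linearized onto one
  int64 axis with large guard gaps, making every statistic a vectorized
  `searchsorted`/prefix-sum computation (a sparse-table range-minimum for
  the containment predicate); this is what keeps 9999 randomizations of a
  453-interval set under a second.

## The synthetic generator

The generator emulates the survey the analysis assumes, with every value a
pure function of (spec, seed):

- **Regions**: 44 regions, thirty pinned at the 0.5 Mb range minimum and
  fourteen uniform in 0.5–2 Mb (the mixed composition of the real pilot
  design, E[total] ≈ 32.5 Mb); `n_minimal_regions=0` gives the plain
  uniform law.  One region per synthetic chromosome with a small nonzero
  genomic offset, so coordinate handling is exercised.
- **Query lengths**: log-normal with median 3423 bp and ln-scale sd 0.8331
  (chosen so the mean matches ~4.8 kb), floored at 1024 bp to emulate the
  1-kb window of the upstream peak caller.  `generate_query_set` places
  them by the null law — it IS a draw from the null, which is what makes
  the calibration tests exact.  `generate_sar_like_set` instead redraws
  placements until all pairwise gaps are ≥ the merge gap, producing the
  disjoint, join-rule-fixed-point shape of a post-processed site table; it
  is the synthetic stand-in used wherever a deposited table would be.
- **Planted targets**: each target independently is forced (probability π)
  to overlap a uniformly chosen query — start uniform over the positions
  guaranteeing ≥ 1 bp overlap inside the region — or placed by the null
  law.  The expected count statistic has a closed form: per-target miss
  probabilities are exact, including incidental overlap of a target forced
  onto one query with a neighbouring query.  The emitted SD of the
  observed count uses the independent-Bernoulli (Poisson-binomial)
  approximation; cross-query covariances are negative, so this slightly
  over-states the spread and the ±3 SD recovery band is conservative.
  `expected_null_count` gives the exact population value the Monte-Carlo
  null mean estimates, by enumerating hit-start positions per query length.
- **Sequences**: independent bases, P(A or T) = 0.65 inside query
  intervals and 0.50 elsewhere, N outside the regions.
- **qPCR panel**: five-point standards per site (slope −3.32, intercept
  30, Ct noise sd 0.1), triplicate scaffold/genomic measurements, 46 of 48
  candidate sites with a planted ratio of 5, sixteen negative regions and
  two control sites.

What the generator does **not** emulate: real base composition and repeat
structure, probe-level array noise, correlated placement of biological
features (genes, timing domains and targets are planted independently
unless π > 0), and length–position dependence.  Passing tests therefore
demonstrate correctness of the statistics and calibration of the null under
the model's own assumptions, not robustness to every property of real
chromatin data.

## Problem sizes used in the checks

The default study (44 regions ≈ 36 Mb, 453 intervals) runs the AT and
enrichment analyses at the full 9999 randomizations.  Null calibration uses
200 replicate datasets of 200 queries × 400 targets at 999 randomizations;
AT calibration uses 100 replicates of a 50-query survey at 199
randomizations; oracle comparisons use 1000 random instances with n, m ≤ 50.
These sizes make the whole suite run in well under a minute while leaving
the Monte-Carlo bands far smaller than the effects they check.

## Known limitations

- The randomization null conditions on interval lengths only; sets with
  strong internal clustering will look enriched against it for any
  clustered target — as with any shuffle-based genomic association test,
  significance is relative to the stated null.
- `bp`-mode statistics on a self-overlapping query set count each query
  interval's intersection separately (observed post-processed sets are
  disjoint; randomized sets may overlap by design).
- The qPCR model is a single log-linear curve: amplification-efficiency
  drift and melt-curve QC are out of scope.
- The reciprocal test randomizes the clipped target set; targets longer
  than every region are rejected rather than trimmed.
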