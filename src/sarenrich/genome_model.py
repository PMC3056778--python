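"""Core genomic data types and file I/O for the SAR analysis pipeline.

Every analysis in this package operates on half-open, 0-based intervals
(``[start, end)``, length ``end - start``) grouped inside a bounded set of
survey regions.  BED input is taken as-is (BED is natively 0-based
half-open); spreadsheet/browser-style tables are treated as 1-based
inclusive and converted on read.  Queries that straddle a survey-region
boundary are excluded (not clipped) from all analyses so that observed and
randomized statistics live on the same support.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sarenrich")

_VALID_STRANDS = (None, "+", "-")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome.

    Coordinates are 0-based; zero-length intervals are rejected.  ``flags``
    carries optional key/value annotations (e.g. ``expressed``).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None
    flags: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            object.__setattr__(self, "start", int(self.start))
            object.__setattr__(self, "end", int(self.end))
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} (use '+', '-' or None)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies wholly inside this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """bp of empty sequence between two intervals on the same chromosome.

        0 for overlapping or book-ended intervals; None across chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" ({self.name})" if self.name else ""
        return f"{self.chrom}:{self.start}-{self.end}{tag}"


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


class RegionSet:
    """The bounded survey regions that constrain randomization and distances.

    Regions are kept sorted on (chrom, start) and must be pairwise
    non-overlapping; all downstream iteration order derives from this sort.
    """

    def __init__(self, regions: Iterable[GenomicInterval]):
        regs = sort_intervals(regions)
        if not regs:
            raise ValueError("RegionSet requires at least one region")
        for a, b in zip(regs, regs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping regions: {a} and {b}")
        self.regions: tuple[GenomicInterval, ...] = tuple(regs)
        self.total_bp: int = sum(r.length for r in regs)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.regions[i]

    def locate(self, iv: GenomicInterval) -> int | None:
        """Index of the region wholly containing *iv*, else None."""
        for i, r in enumerate(self.regions):
            if r.contains(iv):
                return i
        return None

    def touches(self, iv: GenomicInterval) -> bool:
        return any(r.overlaps(iv) for r in self.regions)


@dataclass
class FeatureTrack:
    """A named target interval collection tested for enrichment."""

    track_name: str
    elements: list[GenomicInterval]
    overlap_mode: str = "count"  # count | within_distance | containment | bp
    distance_bp: int = 0

    def __post_init__(self) -> None:
        if self.overlap_mode not in ("count", "within_distance", "containment", "bp"):
            raise ValueError(f"unknown overlap mode {self.overlap_mode!r}")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")

    def clipped_to(self, regions: RegionSet) -> "FeatureTrack":
        """Clip elements to the survey regions.

        Elements wholly outside are dropped; partial overlaps are truncated
        (target tracks, unlike queries, are clipped rather than excluded —
        their bp inside the survey space is what the statistics see).
        """
        out: list[GenomicInterval] = []
        for el in self.elements:
            for r in regions:
                if el.overlaps(r):
                    out.append(
                        dataclasses.replace(
                            el, start=max(el.start, r.start), end=min(el.end, r.end)
                        )
                    )
        return FeatureTrack(
            self.track_name, sort_intervals(out), self.overlap_mode, self.distance_bp
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware TSS/TES and an expression flag."""

    body: GenomicInterval
    expressed: bool = False

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.body.name or self.body} is unstranded; "
                "TSS/TES are undefined"
            )

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (position of the first transcribed base)."""
        return self.body.start if self.body.strand == "+" else self.body.end - 1

    @property
    def tes(self) -> int:
        """Strand-aware 3' end."""
        return self.body.end - 1 if self.body.strand == "+" else self.body.start


@dataclass
class PipelineConfig:
    """Analysis constants.

    ``mat_pvalue_note`` documents the significance threshold of the upstream
    tiling-array peak caller whose interval calls this pipeline consumes; it
    is not used in any computation here.
    """

    merge_gap_bp: int = 2501
    n_randomizations: int = 9999
    proximity_bp: int = 5000
    z_threshold: float = 8.0
    rng_seed: int = 42
    mat_pvalue_note: str = "upstream peak calls at P < 1e-3 (1 kb window)"

    def __post_init__(self) -> None:
        if self.merge_gap_bp <= 0 or self.proximity_bp <= 0 or self.z_threshold <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_bed_line(
    fields: list[str], lineno: int, path: str, expect_strand: bool
) -> GenomicInterval:
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0].strip()
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start >= end or start < 0:
        raise ValueError(f"{path}:{lineno}: invalid span {start}-{end} (start >= end)")
    name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
    strand = None
    if len(fields) > 5 and fields[5] in ("+", "-"):
        strand = fields[5]
    if expect_strand and strand is None:
        raise ValueError(f"{path}:{lineno}: strand required but missing")
    flags = None
    if len(fields) > 6 and fields[6] != "":
        # extended dialect: column 7 carries the expressed {0,1} flag
        flags = {"expressed": fields[6] not in ("0", "false", "False")}
    return GenomicInterval(chrom, start, end, name=name, strand=strand, flags=flags)


def read_bed(path: str | Path, expect_strand: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED6 (tab-delimited, 0-based half-open) into intervals.

    ``track``/``browser``/``#`` header lines are skipped.  An optional 7th
    column is interpreted as the ``expressed`` {0,1} flag of the extended
    gene dialect.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            out.append(_parse_bed_line(line.split("\t"), lineno, str(path), expect_strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None or iv.flags:
                cols.append(iv.name or ".")
            if iv.strand is not None or iv.flags:
                cols += ["0", iv.strand or "."]
            if iv.flags and "expressed" in iv.flags:
                cols.append("1" if iv.flags["expressed"] else "0")
            fh.write("\t".join(cols) + "\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read the extended BED dialect (BED6 + expressed flag) as gene models."""
    genes = []
    for iv in read_bed(path, expect_strand=True):
        expressed = bool(iv.flags.get("expressed", False)) if iv.flags else False
        genes.append(GeneModel(body=iv, expressed=expressed))
    return genes


def to_zero_based(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (inverse of :func:`to_zero_based`)."""
    return start0 + 1, end0


def read_sar_table(
    path: str | Path,
    chrom_col: str = "chrom",
    start_col: str = "start",
    end_col: str = "end",
    name_col: str | None = None,
    one_based: bool = True,
    sheet: str | int = 0,
) -> list[GenomicInterval]:
    """Read a deposited-table-style interval list (CSV/TSV/XLSX).

    Browser/spreadsheet exports are conventionally 1-based inclusive and are
    converted to the internal 0-based half-open convention; pass
    ``one_based=False`` for tables already in BED convention.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    elif suffix == ".tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in (chrom_col, start_col, end_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; detected headers: {list(df.columns)}"
        )
    if df.empty:
        warnings.warn(f"{path}: table has no data rows", stacklevel=2)
        return []
    out = []
    for i, row in df.iterrows():
        s, e = int(row[start_col]), int(row[end_col])
        if one_based:
            s, e = to_zero_based(s, e)
        name = str(row[name_col]) if name_col and name_col in df.columns else None
        out.append(GenomicInterval(str(row[chrom_col]).strip(), s, e, name=name))
    return out


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

@dataclass
class RegionAssignment:
    """Partition of a query set against the survey regions."""

    by_region: dict[int, list[GenomicInterval]]
    straddling: list[GenomicInterval] = field(default_factory=list)
    outside: list[GenomicInterval] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_region.values())

    @property
    def assigned(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for i in sorted(self.by_region):
            out.extend(self.by_region[i])
        return out

    @property
    def region_index(self) -> list[int]:
        """Region index per interval, in the same order as :attr:`assigned`."""
        out: list[int] = []
        for i in sorted(self.by_region):
            out.extend([i] * len(self.by_region[i]))
        return out


def assign_to_regions(
    query: Iterable[GenomicInterval], regions: RegionSet
) -> RegionAssignment:
    """Assign each query wholly inside a region to that region.

    Queries straddling a region boundary or outside all regions are excluded
    with a logged warning count; exclusion (rather than clipping) keeps the
    observed statistics on the randomization null's support.
    """
    by_region: dict[int, list[GenomicInterval]] = {i: [] for i in range(len(regions))}
    straddling: list[GenomicInterval] = []
    outside: list[GenomicInterval] = []
    for iv in sort_intervals(query):
        idx = regions.locate(iv)
        if idx is not None:
            by_region[idx].append(iv)
        elif regions.touches(iv):
            straddling.append(iv)
        else:
            outside.append(iv)
    if straddling or outside:
        logger.warning(
            "assign_to_regions: excluded %d straddling and %d outside interval(s)",
            len(straddling), len(outside),
        )
    return RegionAssignment(by_region=by_region, straddling=straddling, outside=outside)


def check_chrom_compatibility(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[str]:
    """Report chromosome-name prefix mismatches between two interval sets.

    Matching is exact string comparison; this validator surfaces e.g. a
    ``chr1`` vs ``1`` convention clash instead of silently normalizing.
    """
    ca = {iv.chrom for iv in a}
    cb = {iv.chrom for iv in b}
    msgs = []
    only_a, only_b = ca - cb, cb - ca
    for name in sorted(only_a):
        stripped = name.removeprefix("chr")
        if stripped in cb or ("chr" + name) in cb:
            msgs.append(f"chromosome {name!r} vs {('chr' + name) if stripped == name else stripped!r}: prefix mismatch")
    for name in sorted(only_b):
        stripped = name.removeprefix("chr")
        if stripped in ca or ("chr" + name) in ca:
            msg = f"chromosome {name!r} vs {('chr' + name) if stripped == name else stripped!r}: prefix mismatch"
            if msg not in msgs:
                msgs.append(msg)
    for m in msgs:
        logger.warning("check_chrom_compatibility: %s", m)
    return msgs


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

FLOAT_FMT = "%.6g"


def _row_of(obj: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, (list, tuple, np.ndarray)):
                continue  # vector payloads are not row material
            d[f.name] = v
        return d
    if isinstance(obj, Mapping):
        return dict(obj)
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def write_results(
    results: Any, path: str | Path, format: str = "tsv"
) -> None:
    """Write a report object (dataclass rows, dict rows or DataFrame).

    Column/key order is deterministic (declaration order); floats are
    emitted at fixed precision for TSV and round-trip losslessly for JSON.
    """
    path = Path(path)
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown format {format!r}")
    if isinstance(results, pd.DataFrame):
        if format == "tsv":
            results.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        else:
            path.write_text(results.to_json(orient="records", indent=2) + "\n")
        return
    if isinstance(results, Mapping):
        rows = [dict(results)]
    else:
        rows = [_row_of(r) for r in results]
    if format == "json":
        with path.open("w") as fh:
            json.dump(rows if not isinstance(results, Mapping) else rows[0],
                      fh, indent=2, default=str)
            fh.write("\n")
        return
    cols: list[str] = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            cells = []
            for c in cols:
                v = r.get(c, "")
                if isinstance(v, float):
                    cells.append(FLOAT_FMT % v)
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_results_json(path: str | Path) -> Any:
    with Path(path).open() as fh:
        return json.load(fh)
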