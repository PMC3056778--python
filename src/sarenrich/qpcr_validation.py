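"""qPCR validation arithmetic.

Quantities are read off a log-linear standard curve (Ct = intercept +
slope·log10(quantity), slope < 0), the scaffold/genomic quantity ratio per
replicate gives the enrichment of a site in the scaffold fraction, and each
site's mean enrichment is standardized against a negative-control region:

    z = (mean_enrichment − mean(negative)) / sd(negative)      (sd: n−1)

A site validates when z is at or above the configured threshold (default
8).  The false-discovery estimate for a validation panel is
100·(tested − validated)/validated, reported to one decimal (the
alternative denominator, tested, is available via ``denominator``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("site", "fraction", "replicate")


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    positive_slope_warning: bool = False


@dataclass
class QpcrRecord:
    site_name: str
    enrichment_replicates: tuple[float, ...]
    mean_enrichment: float
    z_score: float | None = None
    validated: bool | None = None
    role: str = "candidate"


def fit_standard_curve(points) -> StandardCurve:
    """Least-squares line Ct = intercept + slope·log10(quantity).

    *points* is an iterable of (log10 quantity, Ct) pairs; at least two
    distinct quantities are required.  A positive fitted slope (less
    template giving lower Ct) is flagged but not rejected.
    """
    pts = [(float(x), float(y)) for x, y in points]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(np.unique(xs)) < 2:
        raise ValueError("standard curve needs >= 2 distinct quantities")
    fit = stats.linregress(xs, ys)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(xs),
        positive_slope_warning=fit.slope > 0,
    )


def quantity_from_ct(curve: StandardCurve, ct: float) -> float:
    """Invert the standard curve: quantity = 10^((ct − intercept)/slope)."""
    if curve.slope == 0:
        raise ValueError("cannot invert a flat standard curve")
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def z_scores(
    sites: list[QpcrRecord],
    negative_control_replicates,
    z_threshold: float = 8.0,
) -> list[QpcrRecord]:
    """Standardize each site's mean enrichment against the negative control.

    Requires >= 2 negative-control replicates (so the sample standard
    deviation is defined); sd uses the n−1 denominator.
    """
    neg = np.asarray(list(negative_control_replicates), dtype=float)
    if len(neg) < 2:
        raise ValueError("need >= 2 negative-control replicates")
    sd = float(neg.std(ddof=1))
    if sd == 0:
        raise ValueError("negative-control replicates have zero variance")
    mean_neg = float(neg.mean())
    out = []
    for rec in sites:
        z = (rec.mean_enrichment - mean_neg) / sd
        out.append(
            QpcrRecord(
                site_name=rec.site_name,
                enrichment_replicates=rec.enrichment_replicates,
                mean_enrichment=rec.mean_enrichment,
                z_score=float(z),
                validated=bool(z >= z_threshold),
                role=rec.role,
            )
        )
    return out


def fdr_estimate(
    n_tested: int, n_validated: int, denominator: str = "validated"
) -> float:
    """False-discovery percentage of a validation panel, one decimal.

    Default: 100·(tested − validated)/validated; ``denominator='tested'``
    uses the total panel size instead.  Undefined (NaN) when nothing
    validated.
    """
    if not 0 <= n_validated <= n_tested:
        raise ValueError("need 0 <= n_validated <= n_tested")
    if denominator not in ("validated", "tested"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if n_validated == 0:
        return float("nan")
    denom = n_validated if denominator == "validated" else n_tested
    return round(100.0 * (n_tested - n_validated) / denom, 1)


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited qPCR table.

    Expected columns: site, fraction {scaffold, genomic, standard},
    replicate, and either ct or quantity; standards additionally carry
    log10_quantity.  An optional role column ({candidate, negative,
    control}) marks which sites enter the FDR arithmetic.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; detected: {list(df.columns)}"
        )
    if "ct" not in df.columns and "quantity" not in df.columns:
        raise ValueError(f"{path}: need a 'ct' or 'quantity' column")
    return df


def analyze_qpcr(
    df: pd.DataFrame,
    negative_control: str = "ApoB_neg",
    z_threshold: float = 8.0,
    fdr_denominator: str = "validated",
) -> tuple[list[QpcrRecord], dict]:
    """Full panel analysis: curves -> quantities -> ratios -> Z -> FDR.

    Sites may enter as Ct values (quantified via a per-site standard curve,
    falling back to a pooled curve for sites without their own standards)
    or directly as quantities.  The negative-control site supplies the
    replicate enrichments for standardization.  The summary FDR counts only
    sites whose role is ``candidate`` (everything except the negative
    control when no role column is present).
    """
    df = df.copy()
    roles = {}
    if "role" in df.columns:
        roles = df.groupby("site")["role"].first().to_dict()

    curves: dict[str, StandardCurve] = {}
    standards = df[df["fraction"] == "standard"]
    pooled: StandardCurve | None = None
    if not standards.empty:
        if "log10_quantity" not in standards.columns:
            raise ValueError("standard rows require a log10_quantity column")
        for site, grp in standards.groupby("site"):
            try:
                curves[site] = fit_standard_curve(
                    zip(grp["log10_quantity"], grp["ct"])
                )
            except ValueError:
                pass
        pooled = fit_standard_curve(
            zip(standards["log10_quantity"], standards["ct"])
        )

    def quantify(site: str, row) -> float:
        if "quantity" in df.columns and not pd.isna(row.get("quantity", np.nan)):
            return float(row["quantity"])
        curve = curves.get(site, pooled)
        if curve is None:
            raise ValueError(
                f"site {site}: Ct given but no standard curve available"
            )
        return quantity_from_ct(curve, float(row["ct"]))

    records: list[QpcrRecord] = []
    measured = df[df["fraction"].isin(["scaffold", "genomic"])]
    for site, grp in measured.groupby("site", sort=True):
        ratios = []
        for rep, reps in grp.groupby("replicate"):
            sc = reps[reps["fraction"] == "scaffold"]
            ge = reps[reps["fraction"] == "genomic"]
            if sc.empty or ge.empty:
                continue
            q_s = quantify(site, sc.iloc[0])
            q_g = quantify(site, ge.iloc[0])
            if q_g <= 0:
                raise ValueError(f"site {site} replicate {rep}: non-positive quantity")
            ratios.append(q_s / q_g)
        if not ratios:
            continue
        records.append(
            QpcrRecord(
                site_name=str(site),
                enrichment_replicates=tuple(ratios),
                mean_enrichment=float(np.mean(ratios)),
                role=str(roles.get(site, "candidate" if site != negative_control else "control")),
            )
        )

    neg = next((r for r in records if r.site_name == negative_control), None)
    if neg is None:
        raise ValueError(f"negative control {negative_control!r} not in table")
    scored = z_scores(records, neg.enrichment_replicates, z_threshold)

    candidates = [r for r in scored if r.role == "candidate"]
    n_tested = len(candidates)
    n_validated = sum(1 for r in candidates if r.validated)
    summary = {
        "n_tested": n_tested,
        "n_validated": n_validated,
        "fdr_pct": fdr_estimate(n_tested, n_validated, fdr_denominator)
        if n_validated
        else float("nan"),
        "z_threshold": z_threshold,
        "negative_control": negative_control,
    }
    return scored, summary
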