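"""Standard curves, Z-score validation calls and the FDR arithmetic."""

import numpy as np
import pytest

import sarenrich as sr


# -- standard curve -----------------------------------------------------------

def test_collinear_points_fit_exactly():
    curve = sr.fit_standard_curve([(0, 30.0), (1, 26.68), (2, 23.36)])
    assert curve.slope == pytest.approx(-3.32)
    assert curve.intercept == pytest.approx(30.0)
    assert curve.r_squared == pytest.approx(1.0)
    assert not curve.positive_slope_warning


def test_quantity_inversion_and_round_trip():
    curve = sr.StandardCurve(slope=-3.32, intercept=30.0, r_squared=1.0, n_points=5)
    assert sr.quantity_from_ct(curve, 30.0) == pytest.approx(1.0)
    assert sr.quantity_from_ct(curve, 26.68) == pytest.approx(10.0)
    for q in (0.5, 3.0, 250.0):
        ct = curve.intercept + curve.slope * np.log10(q)
        assert sr.quantity_from_ct(curve, ct) == pytest.approx(q, rel=1e-9)


def test_curve_degenerate_inputs():
    with pytest.raises(ValueError, match="distinct"):
        sr.fit_standard_curve([(1, 30.0), (1, 29.0)])
    warn = sr.fit_standard_curve([(0, 20.0), (1, 25.0)])
    assert warn.positive_slope_warning


def test_noisy_curve_recovers_slope_within_3_se():
    rng = np.random.default_rng(3)
    true_slope, sigma = -3.4, 0.1
    xs = np.arange(5.0)
    ys = 31.0 + true_slope * xs + rng.normal(0, sigma, size=5)
    curve = sr.fit_standard_curve(zip(xs, ys))
    se = sigma / np.sqrt(((xs - xs.mean()) ** 2).sum())
    assert abs(curve.slope - true_slope) < 3 * se
    assert curve.r_squared > 0.99


# -- z scores -----------------------------------------------------------------

def _rec(name, reps):
    return sr.QpcrRecord(name, tuple(reps), float(np.mean(reps)))


def test_z_score_arithmetic_and_threshold():
    (scored,) = sr.z_scores([_rec("s1", [5.0, 5.0, 5.0])], [0.9, 1.0, 1.1])
    assert scored.z_score == pytest.approx(40.0)
    assert scored.validated
    (null,) = sr.z_scores([_rec("s2", [1.0])], [0.9, 1.0, 1.1])
    assert null.z_score == pytest.approx(0.0)
    assert not null.validated


def test_z_score_affine_equivariance():
    sites = [_rec("s", [4.0, 5.0, 6.0])]
    neg = [0.8, 1.0, 1.2]
    (a,) = sr.z_scores(sites, neg)
    scaled = [_rec("s", [40.0, 50.0, 60.0])]
    (b,) = sr.z_scores(scaled, [8.0, 10.0, 12.0])
    assert a.z_score == pytest.approx(b.z_score)


def test_z_score_degenerate_negatives_rejected():
    with pytest.raises(ValueError):
        sr.z_scores([_rec("s", [2.0])], [1.0])
    with pytest.raises(ValueError, match="zero variance"):
        sr.z_scores([_rec("s", [2.0])], [1.0, 1.0, 1.0])


# -- FDR ----------------------------------------------------------------------

@pytest.mark.parametrize("tested,validated,expected", [
    (48, 46, 4.3),
    (48, 48, 0.0),
    (10, 5, 100.0),
])
def test_fdr_estimate_values(tested, validated, expected):
    assert sr.fdr_estimate(tested, validated) == expected


def test_fdr_alternative_denominator_and_monotonicity():
    assert sr.fdr_estimate(48, 46, denominator="tested") == pytest.approx(4.2)
    vals = [sr.fdr_estimate(20, v) for v in range(1, 21)]
    assert vals == sorted(vals, reverse=True)
    assert np.isnan(sr.fdr_estimate(10, 0))
    with pytest.raises(ValueError):
        sr.fdr_estimate(5, 6)


# -- table-level analysis -----------------------------------------------------

def test_panel_recovers_planted_nulls(fast_spec):
    df, truth = sr.generate_qpcr_panel(fast_spec)
    records, summary = sr.analyze_qpcr(df)
    assert summary["n_tested"] == 48
    assert summary["n_validated"] == 46
    assert summary["fdr_pct"] == 4.3
    failed = {r.site_name for r in records if r.role == "candidate" and not r.validated}
    assert failed == set(truth["null_sites"])
    negs = [r for r in records if r.role == "negative"]
    assert len(negs) == 16 and not any(r.validated for r in negs)


def test_noise_free_panel_fits_spec_slope_exactly(fast_spec):
    import dataclasses

    spec = dataclasses.replace(fast_spec, qpcr_noise_sd=0.0)
    df, _ = sr.generate_qpcr_panel(spec, n_sites=2, n_true=2, n_negative=1)
    standards = df[(df["site"] == "site_01") & (df["fraction"] == "standard")]
    curve = sr.fit_standard_curve(zip(standards["log10_quantity"], standards["ct"]))
    assert curve.slope == pytest.approx(spec.qpcr_slope, abs=1e-6)
    assert curve.intercept == pytest.approx(spec.qpcr_intercept, abs=1e-6)


def test_quantity_input_path_equivalent_to_ct_path(fast_spec):
    df, _ = sr.generate_qpcr_panel(fast_spec, n_sites=4, n_true=3, n_negative=2)
    rec_ct, sum_ct = sr.analyze_qpcr(df)
    # convert every measured Ct to a quantity (per-site fitted curve, as the
    # Ct path does) and drop the standards
    meas_rows = []
    for site, grp in df.groupby("site"):
        std = grp[grp["fraction"] == "standard"]
        curve = sr.fit_standard_curve(zip(std["log10_quantity"], std["ct"]))
        m = grp[grp["fraction"] != "standard"].copy()
        m["quantity"] = [sr.quantity_from_ct(curve, ct) for ct in m["ct"]]
        meas_rows.append(m.drop(columns=["ct"]))
    import pandas as pd

    meas = pd.concat(meas_rows, ignore_index=True)
    rec_q, sum_q = sr.analyze_qpcr(meas)
    assert sum_q["n_validated"] == sum_ct["n_validated"]
    za = {r.site_name: r.z_score for r in rec_ct}
    zb = {r.site_name: r.z_score for r in rec_q}
    for site in za:
        assert za[site] == pytest.approx(zb[site], rel=1e-6)


def test_missing_negative_control_is_an_error(fast_spec):
    df, _ = sr.generate_qpcr_panel(fast_spec, n_sites=2, n_true=2, n_negative=0)
    df = df[df["site"] != "ApoB_neg"]
    with pytest.raises(ValueError, match="negative control"):
        sr.analyze_qpcr(df)


def test_read_qpcr_table_validation(tmp_path):
    p = tmp_path / "q.csv"
    p.write_text("site,fraction,replicate\nx,scaffold,1\n")
    with pytest.raises(ValueError, match="ct.*quantity"):
        sr.read_qpcr_table(p)
    p2 = tmp_path / "q2.csv"
    p2.write_text("site,fraction,replicate,ct\nx,scaffold,1,20.0\n")
    assert len(sr.read_qpcr_table(p2)) == 1
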