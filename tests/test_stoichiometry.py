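import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanostoich import (StoichiometryModel, abundance_15n, build_curve,
                        calibrate_stoichiometry, fit_slope, label_fraction,
                        pt_nitrogen_index)
from nanostoich.errors import (ConfigurationError, UndefinedRatioError,
                               UnderdeterminedFitError)
from nanostoich.roi import RoiChannelCounts
from nanostoich.stoichiometry import CurvePoint, StoichiometryCurve


# ---------------------------------------------------------------------------
# abundance


def test_abundance_symmetry_and_pure_label():
    assert abundance_15n(n14=500, n15=500).a == 0.5
    assert abundance_15n(n14=0, n15=300).a == 1.0


def test_abundance_natural_level_with_counting_error(rng):
    ab = abundance_15n(n14=1_000_000, n15=3_690)
    assert ab.a == pytest.approx(3.676e-3, rel=1e-3)
    assert ab.sigma == pytest.approx(6.05e-5, rel=0.02)
    # cross-check σ against binomial resampling of the ¹⁵N split
    total = 1_003_690
    sims = rng.binomial(total, ab.a, 20000) / total
    assert ab.sigma == pytest.approx(sims.std(ddof=1), rel=0.05)


def test_abundance_zero_counts_undefined():
    with pytest.raises(UndefinedRatioError):
        abundance_15n(n14=0, n15=0)


# ---------------------------------------------------------------------------
# label fraction (two-endpoint mixing)


def test_label_fraction_endpoints_are_exact():
    a_ctr, a_cddp = 0.003676, 0.99
    assert label_fraction(a_ctr, a_ctr, a_cddp).x == 0.0
    assert label_fraction(a_cddp, a_ctr, a_cddp).x == 1.0


def test_label_fraction_worked_value():
    lf = label_fraction(0.0040345, 0.00364, 0.99)
    assert lf.x == pytest.approx(4.00e-4, rel=2e-3)
    assert lf.per_mil == pytest.approx(0.400, rel=2e-3)


@settings(derandomize=True, max_examples=200)
@given(a1=st.floats(0.004, 0.5), a2=st.floats(0.004, 0.5))
def test_label_fraction_is_affine_in_abundance(a1, a2):
    """x(λa1 + (1−λ)a2) equals λx1 + (1−λ)x2 to machine precision, and x
    is monotone increasing in the measured abundance."""
    a_ctr, a_cddp = 0.003676, 0.99
    x1 = label_fraction(a1, a_ctr, a_cddp).x
    x2 = label_fraction(a2, a_ctr, a_cddp).x
    mid = label_fraction((a1 + a2) / 2, a_ctr, a_cddp).x
    assert mid == pytest.approx((x1 + x2) / 2, abs=1e-15)
    if a1 > a2:
        assert x1 > x2


def test_marginally_negative_fraction_clipped_and_flagged():
    ab = abundance_15n(n14=100000, n15=330)  # slightly below natural level
    lf = label_fraction(ab, 0.003676, 0.99)
    assert lf.clipped and lf.x == 0.0 and lf.x_raw < 0.0


def test_abundance_far_below_baseline_rejected():
    with pytest.raises(ValueError, match="plausible"):
        label_fraction(0.001, 0.003676, 0.99)


def test_inverted_endpoints_rejected():
    with pytest.raises(ConfigurationError):
        label_fraction(0.5, 0.99, 0.003676)


# ---------------------------------------------------------------------------
# Pt/N index


def _pt_roi(pt=500, c2=10000):
    return RoiChannelCounts("r1", "nucleus", 50, {"194Pt": pt, "12C2": c2})


def _n_roi(n14=24900, n15=100, c2=1000):
    return RoiChannelCounts("r1", "nucleus", 50,
                            {"12C14N": n14, "12C15N": n15, "12C2": c2})


def test_pt_index_direct_arithmetic():
    # Pt/C2 = 0.05 against a CN/C2 average of 25 -> q = 0.002
    idx = pt_nitrogen_index(_pt_roi(), _n_roi())
    assert idx.q == pytest.approx(0.002)
    assert idx.cn_runs_used == ("n_run",)


def test_pt_index_zero_analyte():
    idx = pt_nitrogen_index(_pt_roi(pt=0), _n_roi())
    assert idx.q == 0.0 and idx.upper_bound_only


def test_pt_index_zero_reference_undefined():
    with pytest.raises(UndefinedRatioError):
        pt_nitrogen_index(_pt_roi(c2=0), _n_roi())


def test_pt_index_missing_15n_flagged():
    roi = RoiChannelCounts("r1", "nucleus", 50, {"12C14N": 25000, "12C2": 1000})
    idx = pt_nitrogen_index(_pt_roi(), roi)
    assert idx.missing_15n
    assert idx.q == pytest.approx(0.05 / 25.0)


@settings(derandomize=True, max_examples=100)
@given(g_pt=st.integers(1, 50), g_n=st.integers(1, 50))
def test_pt_index_invariant_under_per_run_gain(g_pt, g_n):
    """Multiplying every channel of each run by a per-run gain leaves the
    index unchanged (ratio-then-average construction)."""
    base = pt_nitrogen_index(_pt_roi(), _n_roi()).q
    scaled = pt_nitrogen_index(_pt_roi(500 * g_pt, 10000 * g_pt),
                               _n_roi(24900 * g_n, 100 * g_n, 1000 * g_n)).q
    assert scaled == pytest.approx(base, rel=1e-12)


def test_pt_index_sigma_matches_poisson_resampling(rng):
    """Propagated σ_q tracks the empirical SD over re-simulated counts."""
    idx = pt_nitrogen_index(_pt_roi(), _n_roi())
    n = 20000
    q = (rng.poisson(500, n) / rng.poisson(10000, n)) / \
        ((rng.poisson(24900, n) + rng.poisson(100, n)) / rng.poisson(1000, n))
    assert idx.sigma_q == pytest.approx(q.std(ddof=1), rel=0.05)


# ---------------------------------------------------------------------------
# curves, fits, calibration


def test_build_curve_hand_statistics():
    df = pd.DataFrame({
        "compartment": ["nucleolus"] * 3,
        "concentration": [25.0] * 3,
        "q": [0.001, 0.002, 0.003],
        "x": [1e-4, 2e-4, 3e-4],
    })
    curve = build_curve(df, "nucleolus")
    (p,) = curve.points
    assert p.x == pytest.approx(2e-4)
    assert p.x_sd == pytest.approx(1e-4)
    assert p.n_rois == 3


def test_build_curve_orders_points_by_concentration():
    df = pd.DataFrame({
        "compartment": ["c"] * 3,
        "concentration": [100.0, 0.0, 25.0],
        "q": [3.0, 0.0, 1.0],
        "x": [0.3, 0.0, 0.1],
    })
    concs = [p.concentration for p in build_curve(df, "c").points]
    assert concs == [0.0, 25.0, 100.0]


def test_build_curve_missing_compartment_rejected():
    df = pd.DataFrame({"compartment": ["c"], "concentration": [0.0],
                       "q": [0.0], "x": [0.0]})
    with pytest.raises(ValueError, match="no measurements"):
        build_curve(df, "nucleolus")


def _curve(points):
    return StoichiometryCurve("c", [
        CurvePoint(float(i), q, x, 0.0, 0.0, 0.0, 0.0, 1)
        for i, (q, x) in enumerate(points)])


def test_fit_slope_exact_on_collinear_points():
    fit = fit_slope(_curve([(0, 0), (0.001, 2e-4), (0.002, 4e-4)]))
    assert fit.slope == pytest.approx(0.2, abs=1e-12)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.origin_slope == pytest.approx(0.2, abs=1e-12)


def test_fit_slope_underdetermined():
    with pytest.raises(UnderdeterminedFitError):
        fit_slope(_curve([(0.001, 1e-4), (0.001, 2e-4)]))


def test_fit_slope_inverse_variance_weighting_prefers_precise_points():
    pts = [CurvePoint(0.0, 0.0, 0.0, 0.0, 1e-6, 0.0, 1e-6, 3),
           CurvePoint(1.0, 0.001, 2e-4, 0.0, 1e-6, 0.0, 1e-6, 3),
           # wildly off but 1000x noisier point
           CurvePoint(2.0, 0.002, 5e-3, 0.0, 1e-3, 0.0, 1e-3, 3)]
    fit = fit_slope(StoichiometryCurve("c", pts), weighting="inverse-variance")
    assert fit.slope == pytest.approx(0.2, rel=0.05)


def test_calibration_identities():
    assert calibrate_stoichiometry(0.0, 90.0, 10.0).ratio == 0.0
    one = calibrate_stoichiometry(0.222, 90.0, 10.0)
    doubled = calibrate_stoichiometry(0.222, 180.0, 20.0)
    assert one.ratio == pytest.approx(doubled.ratio)
    missing = calibrate_stoichiometry(0.222)
    assert not missing.calibrated and math.isnan(missing.ratio)
    assert missing.slope == 0.222


def test_model_results_summary_and_params(series_config):
    df = pd.DataFrame({
        "compartment": ["a"] * 4 + ["b"] * 4,
        "concentration": [0, 10, 50, 100] * 2,
        "q": [0, 1, 5, 10, 0, 1, 5, 10],
        "x": [0, 0.2, 1.0, 2.0, 0, 0.1, 0.5, 1.0],
    })
    res = StoichiometryModel(df).fit()
    assert res.params.loc["a", "slope"] == pytest.approx(0.2, abs=1e-12)
    assert res.params.loc["b", "slope"] == pytest.approx(0.1, abs=1e-12)
    cal = res.calibrate(10.0, 1.0)
    assert cal.loc["a", "n_per_pt"] == pytest.approx(2.0, abs=1e-10)
    text = res.summary()
    assert "slope" in text and "a" in text
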