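import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nanostoich import IonCountMap, colocalise, compare_groups
from nanostoich.channels import channel
from nanostoich.errors import DegenerateVarianceError, UndefinedRatioError


def student_t_oracle(a, b):
    """Textbook pooled-variance two-sample t: independent of the
    implementation under test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def test_identical_groups_give_t_zero_p_one():
    res = compare_groups([1, 2, 3], [1, 2, 3])
    assert res.t == 0.0
    assert res.p == pytest.approx(1.0)


def test_zero_pooled_variance_rejected():
    with pytest.raises(DegenerateVarianceError):
        compare_groups([0, 0], [0, 0])


def test_matches_textbook_oracle_on_fixed_data():
    a, b = [1.1, 1.9, 1.5, 1.4], [2.8, 3.1, 2.6, 3.3]
    res = compare_groups(a, b)
    t, p = student_t_oracle(a, b)
    assert res.t == pytest.approx(t, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)


def test_welch_variant_differs_under_unequal_variance():
    a = [1.0, 1.1, 0.9, 1.05, 0.95]
    b = [2.0, 4.0, 0.5, 3.5, 1.0]
    student = compare_groups(a, b, variant="student")
    welch = compare_groups(a, b, variant="welch")
    assert student.p != welch.p


# ---------------------------------------------------------------------------
# colocalisation


def _map(counts, label="34S"):
    return IonCountMap(channel(label), np.asarray(counts), 0.07, 250.0)


def test_identical_channels_fully_colocalise(rng):
    img = rng.poisson(30.0, (40, 40))
    # classic zero-threshold Manders: all intensity overlaps itself
    res = colocalise(_map(img), _map(img, "194Pt"), thresholds=(0, 0))
    assert res.pearson_r == pytest.approx(1.0)
    assert res.manders_m1 == pytest.approx(1.0)
    assert res.manders_m2 == pytest.approx(1.0)
    # with Otsu thresholds the overlap stays symmetric for identical maps
    otsu = colocalise(_map(img), _map(img, "194Pt"))
    assert otsu.manders_m1 == pytest.approx(otsu.manders_m2)


def test_inverted_channel_anticorrelates(rng):
    img = rng.poisson(30.0, (40, 40))
    res = colocalise(_map(img), _map(img.max() - img, "194Pt"))
    assert res.pearson_r == pytest.approx(-1.0)


def test_constant_channel_is_undefined(rng):
    img = rng.poisson(30.0, (20, 20))
    with pytest.raises(UndefinedRatioError):
        colocalise(_map(img), _map(np.full((20, 20), 5), "194Pt"))


def test_scope_restricts_to_compartment(small_phantom):
    pt, _, truth = small_phantom
    res = colocalise(pt.channel("34S"), pt.channel("19F"),
                     mask=truth.mask, scope="cytoplasm")
    assert res.n_pixels == truth.mask.compartment_pixels("cytoplasm").sum()
    assert res.scope == "cytoplasm"
    assert res.threshold_method == "otsu"


def test_fixed_thresholds_recorded(rng):
    img = rng.poisson(30.0, (20, 20))
    res = colocalise(_map(img), _map(img + 1, "194Pt"), thresholds=(10, 12))
    assert (res.threshold_a, res.threshold_b) == (10.0, 12.0)
    assert res.threshold_method == "fixed"


def test_independent_channels_show_no_correlation():
    """Independent Poisson images stay |r| < 0.05 at 10⁴ pixels in at
    least 95% of seeded replicates (null calibration)."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a = rng.poisson(30.0, (100, 100))
        b = rng.poisson(50.0, (100, 100))
        if abs(colocalise(_map(a), _map(b, "194Pt")).pearson_r) < 0.05:
            hits += 1
    assert hits >= 95


@settings(derandomize=True, max_examples=50)
@given(scale=st.integers(1, 50), offset=st.integers(0, 100))
def test_pearson_invariant_under_affine_rescaling(scale, offset):
    """r is unchanged by a positive affine map of either channel (counts
    stay integral, so gains/offsets are integer-valued here)."""
    rng = np.random.default_rng(99)
    img_a = rng.poisson(30.0, (25, 25))
    img_b = rng.poisson(30.0, (25, 25)) + img_a
    base = colocalise(_map(img_a), _map(img_b, "194Pt")).pearson_r
    res = colocalise(_map(img_a), _map(img_b * scale + offset, "194Pt")).pearson_r
    assert res == pytest.approx(base, abs=1e-9)
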