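import dataclasses
import math

import numpy as np
import pytest

from nanostoich import (PhantomConfig, central_section_volume_fraction,
                        generate_phantom, linear_accumulation,
                        nested_exposure_series)
from nanostoich.errors import ConfigurationError
from nanostoich.roi import extract_roi_counts


def test_identical_seed_gives_bit_identical_stacks(small_config):
    pt1, n1, t1 = generate_phantom(small_config)
    pt2, n2, t2 = generate_phantom(small_config)
    for a, b in ((pt1, pt2), (n1, n2)):
        for lbl in a.maps:
            np.testing.assert_array_equal(a.maps[lbl].counts, b.maps[lbl].counts)
    np.testing.assert_array_equal(t1.mask.labels, t2.mask.labels)


def test_different_seed_changes_counts(small_config):
    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    pt1, _, _ = generate_phantom(small_config)
    pt2, _, _ = generate_phantom(other)
    assert (pt1.channel("12C2").counts != pt2.channel("12C2").counts).any()


def test_zero_drug_abundance_matches_control_baseline(small_phantom, small_config):
    """With no drug anywhere, every compartment's measured ¹⁵N abundance
    sits at the natural baseline within 3 Monte-Carlo standard errors."""
    _, n_run, truth = small_phantom
    for roi in extract_roi_counts(n_run, truth.mask):
        n14, n15 = roi.counts["12C14N"], roi.counts["12C15N"]
        a = n15 / (n14 + n15)
        se = math.sqrt(a * (1 - a) / (n14 + n15))
        assert abs(a - small_config.a_ctr) < 3 * se


def test_roi_summed_pt_counts_match_configured_rate(small_config):
    """Expected 5 Pt counts/pixel in the nucleolus: the ROI sum over its
    pixels lands within Poisson tolerance of rate x area."""
    cfg = dataclasses.replace(
        small_config, drug_load={**small_config.drug_load, "nucleolus": 5.0})
    pt, _, truth = generate_phantom(cfg)
    (roi,) = [r for r in extract_roi_counts(pt, truth.mask)
              if r.compartment == "nucleolus"]
    expected = 5.0 * roi.pixel_count
    assert abs(roi.counts["194Pt"] - expected) <= 3 * math.sqrt(expected)


def test_counts_are_poisson_dispersed_within_compartments(small_phantom):
    """Index of dispersion (variance/mean) ≈ 1 in homogeneous regions."""
    pt, _, truth = small_phantom
    counts = pt.channel("12C2").counts
    for name in ("cytoplasm", "nucleus"):
        sel = counts[truth.mask.compartment_pixels(name)].astype(float)
        iod = sel.var(ddof=1) / sel.mean()
        # for n pixels the null spread of the IoD is ~sqrt(2/n)
        assert abs(iod - 1.0) < 4 * math.sqrt(2.0 / sel.size)


def test_geometry_is_nested_and_mutually_exclusive(small_phantom):
    _, _, truth = small_phantom
    mask = truth.mask
    assert set(mask.legend.values()) <= {"cytoplasm", "nucleus", "nucleolus",
                                         "chromatin", "aggregate"}
    # one label per pixel by construction; every compartment non-empty
    for comp in ("cytoplasm", "nucleus", "nucleolus", "chromatin", "aggregate"):
        assert mask.compartment_pixels(comp).sum() > 0
    # nucleolus and chromatin never overlap cytoplasm or each other
    assert not (mask.compartment_pixels("nucleolus")
                & mask.compartment_pixels("chromatin")).any()


def test_zero_shift_gives_aligned_masks(small_config):
    pt, n_run, truth = generate_phantom(small_config)
    assert truth.inter_run_shift == (0, 0)
    # nucleolus pixels are bright in CN on the n_run at the same coordinates
    sel = truth.mask.compartment_pixels("nucleolus")
    cn = n_run.channel("12C14N").counts
    assert cn[sel].mean() > 1.5 * cn[~sel].mean()


def test_inter_run_shift_moves_nitrogen_frame(small_config):
    cfg = dataclasses.replace(small_config, inter_run_shift=(4, -6))
    pt, n_run, truth = generate_phantom(cfg)
    shifted = truth.mask.shifted(4, -6)
    sel = shifted.compartment_pixels("nucleolus")
    cn = n_run.channel("12C14N").counts
    assert cn[sel].mean() > 1.5 * cn[~sel].mean()


def test_oversized_cell_raises_configuration_error():
    with pytest.raises(ConfigurationError, match="fit"):
        generate_phantom(PhantomConfig(grid=(64, 64), pixel_size=36 / 64,
                                       cell_radius=17.0, nucleus_radius=8.0,
                                       nucleolus_radius=1.0))


def test_non_nested_geometry_rejected():
    with pytest.raises(ConfigurationError, match="nest"):
        PhantomConfig(nucleolus_radius=3.0, nucleus_radius=2.5)


def test_exposure_series_structure(small_config):
    concs = [0, 2.5, 5, 10, 25, 50, 100, 150]
    series = nested_exposure_series(small_config, concs)
    assert len(series) == 8
    assert series[0][0].is_control
    # drug loads monotone non-decreasing in concentration per compartment
    pt_means = [t.pt_index["nucleolus"] for _, _, t in series]
    assert all(b >= a for a, b in zip(pt_means, pt_means[1:]))


def test_control_only_series_has_zero_truth(small_config):
    ((pt, n_run, truth),) = nested_exposure_series(small_config, [0.0])
    assert all(v == 0.0 for v in truth.label_fraction.values())
    assert pt.is_control and n_run.is_control


def test_linear_accumulation_gives_proportional_truth(small_config):
    """With loads linear in concentration and stoichiometry fixed, the true
    label fraction is proportional to the true Pt index in every
    compartment (the analytic line the pipeline should recover)."""
    series = nested_exposure_series(small_config, [0, 50, 100, 150],
                                    linear_accumulation())
    slope = small_config.ligand_retention["cytoplasm"] * \
        small_config.rsf_cn / small_config.rsf_pt
    for _, _, truth in series:
        for comp in truth.label_fraction:
            assert truth.label_fraction[comp] == pytest.approx(
                slope * truth.pt_index[comp], rel=1e-12)


def test_empty_concentration_list_rejected(small_config):
    with pytest.raises(ConfigurationError, match="empty"):
        nested_exposure_series(small_config, [])


def test_non_monotone_accumulation_rejected(small_config):
    with pytest.raises(ConfigurationError, match="monotone"):
        nested_exposure_series(small_config, [0, 10, 20],
                               lambda comp, c: max(0.0, 10.0 - c))


def test_section_volume_fraction_against_numerical_integral():
    """Analytic slab fraction agrees with direct numerical integration of
    the sphere's cross-sectional area."""
    from scipy.integrate import quad

    r, t = 5.0, 0.3
    slab, _ = quad(lambda z: math.pi * (r * r - z * z), -t / 2, t / 2)
    expected = slab / (4.0 / 3.0 * math.pi * r ** 3)
    assert central_section_volume_fraction(t, 2 * r) == pytest.approx(
        expected, abs=1e-14)
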