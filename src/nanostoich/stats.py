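"""Group comparisons and channel-pair colocalisation metrics.

Treated-versus-control comparisons of ROI ratio values use the classical
two-sample, two-tailed, equal-variance Student's t-test by default (a
Welch option is exposed); no multiple-testing correction is applied.
Colocalisation of two ion channels within a compartment is quantified by
the Pearson correlation of in-scope pixel intensities and the Manders
overlap coefficients M1/M2 with per-channel Otsu (or fixed) thresholds —
a quantitative stand-in for the visual overlap assessment of Pt with
S-rich aggregates and the ¹⁹F⁻ lysosomal tracer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.filters import threshold_otsu

from .errors import DegenerateVarianceError, DimensionMismatchError, UndefinedRatioError
from .io import IonCountMap
from .roi import CompartmentMask


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test result."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    p: float
    variant: str  # "student" or "welch"


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   label_a: str = "a", label_b: str = "b",
                   variant: str = "student") -> GroupComparison:
    """Two-tailed two-sample t-test between two groups of ROI values.

    ``variant="student"`` pools variances (the classical test);
    ``variant="welch"`` drops the equal-variance assumption.  Each group
    needs ≥2 values and the pooled variance must be nonzero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    pooled_ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if pooled_ss == 0:
        raise DegenerateVarianceError("zero pooled variance between the groups")
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return GroupComparison(label_a, label_b, len(a), len(b),
                           float(a.mean()), float(b.mean()),
                           float(t), float(p), variant)


@dataclass(frozen=True)
class ColocalisationResult:
    """Pearson and Manders colocalisation of two channels within a scope."""

    channel_a: str
    channel_b: str
    scope: str
    n_pixels: int
    pearson_r: float
    manders_m1: float
    manders_m2: float
    threshold_a: float
    threshold_b: float
    threshold_method: str


def colocalise(map_a: IonCountMap, map_b: IonCountMap,
               mask: CompartmentMask | None = None,
               scope: str = "all",
               thresholds: tuple[float, float] | None = None) -> ColocalisationResult:
    """Colocalisation of two ion channels over one compartment's pixels.

    Pearson r is computed over the in-scope pixel intensities.  Manders
    M1 is the fraction of channel-a intensity falling on pixels where
    channel b exceeds its threshold (M2 symmetric); thresholds default to
    per-channel Otsu on the in-scope pixels, and the choice is recorded
    in the result.
    """
    if map_a.shape != map_b.shape:
        raise DimensionMismatchError("maps must share dimensions")
    if mask is None or scope == "all":
        in_scope = np.ones(map_a.shape, dtype=bool)
    else:
        in_scope = mask.compartment_pixels(scope)
        if mask.shape != map_a.shape:
            raise DimensionMismatchError("mask dims differ from map dims")
    if not in_scope.any():
        raise ValueError(f"scope {scope!r} selects no pixels")
    a = map_a.counts[in_scope].astype(np.float64)
    b = map_b.counts[in_scope].astype(np.float64)
    if a.std() == 0 or b.std() == 0:
        raise UndefinedRatioError(
            "constant channel within scope: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])

    if thresholds is None:
        t_a = float(threshold_otsu(a))
        t_b = float(threshold_otsu(b))
        method = "otsu"
    else:
        t_a, t_b = map(float, thresholds)
        method = "fixed"
    sum_a = a.sum()
    sum_b = b.sum()
    m1 = float(a[b > t_b].sum() / sum_a) if sum_a > 0 else float("nan")
    m2 = float(b[a > t_a].sum() / sum_b) if sum_b > 0 else float("nan")
    return ColocalisationResult(
        map_a.channel.species_label, map_b.channel.species_label, scope,
        int(in_scope.sum()), r, m1, m2, t_a, t_b, method)
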