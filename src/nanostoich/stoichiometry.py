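"""Isotope label fractions, Pt/N indices and stoichiometry slope fits.

The quantitative chain implemented here turns ROI count sums into a
ligand-to-metal stoichiometry monitor:

1. **¹⁵N abundance** ``a = n15 / (n14 + n15)`` from the ¹²C¹⁵N⁻ and
   ¹²C¹⁴N⁻ ROI sums, with binomial counting error
   ``σ_a = sqrt(a(1−a)/(n14+n15))``.

2. **Label fraction** — the fraction of a region's nitrogen atoms that
   originates from the administered ¹⁵N-labelled drug.  Two-endpoint
   isotope mixing between the untreated control abundance ``a_ctr`` and
   the compound's label purity ``a_cddp``::

       x = (a_tot − a_ctr) / (a_cddp − a_ctr)

   This relation is exact (no further assumptions): the measured
   abundance is the atom-weighted mean of the two nitrogen pools.
   Display unit is per mil; stored values are fractions.

3. **Pt/N index** — SIMS is only semi-quantitative for elemental
   analysis, but with the ¹²C₂⁻ signal as internal reference a quantity
   proportional to the Pt/N_tot concentration ratio can be formed::

       q = [I(¹⁹⁴Pt)/I(¹²C₂)]_pt ÷ [I(¹²C¹⁴N)+I(¹²C¹⁵N))/I(¹²C₂)]_avg

   where the ``avg`` bracket is the mean of the CN/C₂ ratio over the
   runs that record CN channels.  Forming per-run ratios first makes the
   index exactly invariant under per-run multiplicative gains.

4. **Stoichiometry curves** — per compartment, (q, x) across the
   exposure series.  The slope of x versus q is proportional to the
   N/Pt stoichiometry of the accumulated drug (2 for the intact
   cis-diammine compound); flattening indicates ammine-ligand cleavage.
   When relative sensitivity factors are known (phantoms), the slope
   calibrates to an absolute N:Pt atom ratio as
   ``ratio = slope × rsf_pt / rsf_cn`` — the (a_cddp − a_ctr) scale is
   already absorbed by the label-fraction denominator.

The model/results interface follows the usual statistical-modelling
pattern: :class:`StoichiometryModel` is built from a tidy per-ROI
measurement table; ``fit()`` returns a :class:`StoichiometryResults`
carrying per-compartment curves, slope estimates with standard errors,
calibration and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, UndefinedRatioError, UnderdeterminedFitError
from .roi import RoiChannelCounts

# ---------------------------------------------------------------------------
# abundance and label fraction


@dataclass(frozen=True)
class IsotopeAbundance:
    """¹⁵N/(¹⁴N+¹⁵N) with its counting error."""

    a: float
    sigma: float
    n14: int
    n15: int


def abundance_15n(roi: RoiChannelCounts | None = None, *,
                  n14: int | None = None, n15: int | None = None) -> IsotopeAbundance:
    """¹⁵N isotopic abundance of an ROI from its CN⁻ count sums.

    Accepts either an ``n_run`` :class:`~nanostoich.roi.RoiChannelCounts`
    or raw ``n14``/``n15`` sums.  The counting error treats the ¹⁵N count
    as binomial in the total CN count: ``σ = sqrt(a(1−a)/(n14+n15))``.
    """
    if roi is not None:
        n14 = roi.counts["12C14N"]
        n15 = roi.counts["12C15N"]
    if n14 is None or n15 is None:
        raise ValueError("provide an ROI or both n14 and n15")
    if n14 < 0 or n15 < 0:
        raise ValueError("counts must be non-negative")
    total = n14 + n15
    if total == 0:
        raise UndefinedRatioError("zero total CN counts: abundance undefined")
    a = n15 / total
    sigma = math.sqrt(a * (1.0 - a) / total)
    return IsotopeAbundance(a, sigma, int(n14), int(n15))


@dataclass(frozen=True)
class LabelFraction:
    """Fraction of nitrogen originating from the labelled drug (Eq. 1 sense).

    ``x`` is the physically reported fraction, clipped to 0 when counting
    noise pushes the measured abundance marginally below the control
    baseline (always flagged via ``clipped``).  ``x_raw`` keeps the
    unclipped value: regression across an exposure series must use it,
    because clipping an unbiased noisy estimator at zero biases
    low-concentration means upward and flattens fitted slopes.
    """

    x: float
    sigma_x: float
    a_tot: float
    a_ctr: float
    a_cddp: float
    clipped: bool = False
    x_raw: float = 0.0

    @property
    def per_mil(self) -> float:
        return 1000.0 * self.x


def label_fraction(a_tot: IsotopeAbundance | float, a_ctr: float,
                   a_cddp: float) -> LabelFraction:
    """Two-endpoint mixing: ``x = (a_tot − a_ctr)/(a_cddp − a_ctr)``.

    Affine and strictly increasing in ``a_tot``; ``x(a_ctr) = 0`` and
    ``x(a_cddp) = 1`` exactly.  Values marginally below the control
    baseline (within 5 counting errors) are clipped to 0 and flagged —
    the label fraction is a physical fraction; values outside
    ``[a_ctr − 5σ, a_cddp]`` raise.
    """
    if a_cddp <= a_ctr:
        raise ConfigurationError("a_cddp must exceed a_ctr")
    if isinstance(a_tot, IsotopeAbundance):
        a, sigma = a_tot.a, a_tot.sigma
    else:
        a, sigma = float(a_tot), 0.0
    if a > a_cddp or a < a_ctr - 5.0 * sigma:
        raise ValueError(
            f"abundance {a} outside plausible range "
            f"[{a_ctr} − 5σ, {a_cddp}]")
    span = a_cddp - a_ctr
    x_raw = (a - a_ctr) / span
    sigma_x = sigma / span
    clipped = x_raw < 0
    x = 0.0 if clipped else x_raw
    return LabelFraction(x, sigma_x, a, a_ctr, a_cddp, clipped, x_raw)


# ---------------------------------------------------------------------------
# Pt/N index


@dataclass(frozen=True)
class PtNitrogenIndex:
    """Reference-normalised Pt/N quantity with propagated counting error."""

    q: float
    sigma_q: float
    pt_ratio: float          # (I_Pt / I_C2) from the platinum run
    cn_ratio_avg: float      # mean (I_CN / I_C2) over the CN-recording runs
    cn_runs_used: tuple[str, ...] = ()
    missing_15n: bool = False
    upper_bound_only: bool = False


def _cn_over_c2(roi: RoiChannelCounts) -> tuple[float, float, bool] | None:
    """(ratio, relative variance, missing-¹⁵N flag) for one run's ROI, or None."""
    if "12C14N" not in roi.counts:
        return None
    n14 = roi.counts["12C14N"]
    missing_15n = "12C15N" not in roi.counts
    cn = n14 + (0 if missing_15n else roi.counts["12C15N"])
    c2 = roi.counts["12C2"]
    if c2 <= 0:
        raise UndefinedRatioError("zero 12C2 reference counts")
    if cn <= 0:
        raise UndefinedRatioError("zero CN counts in reference run")
    ratio = cn / c2
    rel_var = 1.0 / cn + 1.0 / c2
    return ratio, rel_var, missing_15n


def pt_nitrogen_index(pt_roi: RoiChannelCounts,
                      n_roi: RoiChannelCounts) -> PtNitrogenIndex:
    """Pt/N index of one ROI from its paired platinum and nitrogen runs.

    The numerator is the ¹²C₂⁻-normalised ¹⁹⁴Pt⁻ intensity of the
    platinum run; the denominator averages the ¹²C₂⁻-normalised total
    CN⁻ intensity over whichever of the two runs record CN channels.
    Where only ¹²C¹⁴N⁻ is recorded it stands in for the total with a
    flag (the bias equals the ¹⁵N abundance, well below counting error
    at tracer-level enrichment).  First-order Poisson propagation over
    all contributing counts yields ``sigma_q``.
    """
    n_pt = pt_roi.counts["194Pt"]
    c2_pt = pt_roi.counts["12C2"]
    if c2_pt <= 0:
        raise UndefinedRatioError("zero 12C2 reference counts in pt run")

    terms = []
    runs = []
    missing = False
    for name, roi in (("pt_run", pt_roi), ("n_run", n_roi)):
        got = _cn_over_c2(roi)
        if got is not None:
            terms.append(got[:2])
            missing = missing or got[2]
            runs.append(name)
    if not terms:
        raise UndefinedRatioError("no run records CN channels")
    m = len(terms)
    cn_avg = sum(r for r, _ in terms) / m
    var_avg = sum((r * r * rv) for r, rv in terms) / (m * m)
    rel_var_avg = var_avg / (cn_avg * cn_avg)

    if n_pt == 0:
        # no analyte: index 0 with a one-sided counting-scale upper bound
        sigma = (1.0 / c2_pt) / cn_avg
        return PtNitrogenIndex(0.0, sigma, 0.0, cn_avg, tuple(runs),
                               missing, upper_bound_only=True)
    pt_ratio = n_pt / c2_pt
    q = pt_ratio / cn_avg
    rel_var = 1.0 / n_pt + 1.0 / c2_pt + rel_var_avg
    return PtNitrogenIndex(q, q * math.sqrt(rel_var), pt_ratio, cn_avg,
                           tuple(runs), missing)


# ---------------------------------------------------------------------------
# curves and fits


@dataclass(frozen=True)
class CurvePoint:
    """One exposure concentration's compartment mean over ROI replicates."""

    concentration: float
    q: float
    x: float
    q_sd: float          # across-ROI dispersion (the error-bar quantity)
    x_sd: float
    sigma_q: float       # mean counting error (precision measure)
    sigma_x: float
    n_rois: int


@dataclass
class StoichiometryCurve:
    """Per-compartment (Pt index, label fraction) points across exposures."""

    compartment: str
    points: list[CurvePoint]

    def __post_init__(self):
        self.points = sorted(self.points, key=lambda p: p.concentration)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.points])


_MEASUREMENT_COLUMNS = ("compartment", "concentration", "q", "x")


def build_curve(measurements: pd.DataFrame,
                compartment: str) -> StoichiometryCurve:
    """Aggregate per-ROI measurements into one compartment's curve.

    ``measurements`` is the tidy per-ROI table (columns ``compartment``,
    ``concentration``, ``q``, ``x`` and optionally ``sigma_q``,
    ``sigma_x``).  Per concentration the ROI replicates are averaged;
    the across-ROI standard deviation is the dispersion the error bars
    show, kept separate from the mean counting error.
    """
    for col in _MEASUREMENT_COLUMNS:
        if col not in measurements.columns:
            raise ValueError(f"measurement table lacks column {col!r}")
    sub = measurements[measurements["compartment"] == compartment]
    if sub.empty:
        raise ValueError(f"no measurements for compartment {compartment!r}")
    points = []
    for conc, grp in sub.groupby("concentration"):
        points.append(CurvePoint(
            concentration=float(conc),
            q=float(grp["q"].mean()),
            x=float(grp["x"].mean()),
            q_sd=float(grp["q"].std(ddof=1)) if len(grp) > 1 else 0.0,
            x_sd=float(grp["x"].std(ddof=1)) if len(grp) > 1 else 0.0,
            sigma_q=float(grp["sigma_q"].mean()) if "sigma_q" in grp else 0.0,
            sigma_x=float(grp["sigma_x"].mean()) if "sigma_x" in grp else 0.0,
            n_rois=int(len(grp)),
        ))
    return StoichiometryCurve(compartment, points)


@dataclass(frozen=True)
class SlopeFit:
    """Weighted least-squares fit of label fraction on Pt index."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    origin_slope: float       # restricted through-origin comparison fit
    origin_slope_se: float
    n_points: int
    weighting: str


def _point_weights(curve: StoichiometryCurve, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones(len(curve.points))
    if weighting != "inverse-variance":
        raise ValueError("weighting must be 'none' or 'inverse-variance'")
    w = []
    for p in curve.points:
        # variance of the point mean: ROI dispersion when replicated,
        # else the counting error
        if p.n_rois > 1 and p.x_sd > 0:
            var = (p.x_sd ** 2) / p.n_rois
        elif p.sigma_x > 0:
            var = p.sigma_x ** 2
        else:
            var = np.nan
        w.append(var)
    var = np.asarray(w)
    if np.isnan(var).all():
        return np.ones(len(curve.points))
    fallback = np.nanmax(var)
    var = np.where(np.isnan(var) | (var <= 0), fallback, var)
    return 1.0 / var


def fit_slope(curve: StoichiometryCurve,
              weighting: str = "none") -> SlopeFit:
    """Fit ``x = intercept + slope·q`` over the curve's points.

    Returns the free-intercept fit (the intercept is a QC diagnostic:
    it should include 0 after control subtraction) plus a restricted
    through-origin slope for comparison.  Exactly collinear points
    reproduce the line to machine precision.
    """
    q = np.array([p.q for p in curve.points], dtype=float)
    x = np.array([p.x for p in curve.points], dtype=float)
    if len(np.unique(q)) < 2:
        raise UnderdeterminedFitError(
            f"compartment {curve.compartment}: <2 distinct q values")
    w = _point_weights(curve, weighting)
    free = sm.WLS(x, sm.add_constant(q), weights=w).fit()
    origin = sm.WLS(x, q[:, None], weights=w).fit()
    se = free.bse
    return SlopeFit(
        slope=float(free.params[1]),
        slope_se=float(se[1]) if np.isfinite(se[1]) else float("nan"),
        intercept=float(free.params[0]),
        intercept_se=float(se[0]) if np.isfinite(se[0]) else float("nan"),
        origin_slope=float(origin.params[0]),
        origin_slope_se=float(origin.bse[0]) if np.isfinite(origin.bse[0]) else float("nan"),
        n_points=len(q),
        weighting=weighting,
    )


@dataclass(frozen=True)
class CalibratedStoichiometry:
    """N:Pt atom ratio obtained from a slope and known sensitivity factors."""

    ratio: float
    ratio_se: float
    slope: float
    calibrated: bool

    def __post_init__(self):
        if self.calibrated and self.ratio < 0 and self.ratio < -5 * max(self.ratio_se, 0):
            raise ValueError("calibrated stoichiometry significantly negative")


def calibrate_stoichiometry(slope: float, rsf_pt: float | None = None,
                            rsf_cn: float | None = None,
                            slope_se: float = float("nan")
                            ) -> CalibratedStoichiometry:
    """Convert a curve slope to an N:Pt atom ratio using known RSFs.

    With count rates ``I_Pt = rsf_pt·n_Pt`` and ``I_CN = rsf_cn·n_N`` the
    index is ``q = (rsf_pt/rsf_cn)·(n_Pt/n_N)`` while the label fraction
    is the atom ratio itself, so ``ratio = slope · rsf_pt / rsf_cn`` —
    exact on noise-free inputs and invariant under a consistent
    rescaling of both RSFs.  On real samples the RSFs are unknown; the
    result is then flagged uncalibrated and carries the raw slope.
    """
    if rsf_pt is None or rsf_cn is None:
        return CalibratedStoichiometry(float("nan"), float("nan"),
                                       float(slope), calibrated=False)
    if rsf_pt <= 0 or rsf_cn <= 0:
        raise ConfigurationError("sensitivity factors must be positive")
    scale = rsf_pt / rsf_cn
    return CalibratedStoichiometry(float(slope) * scale,
                                   float(slope_se) * scale,
                                   float(slope), calibrated=True)


# ---------------------------------------------------------------------------
# model / results


class StoichiometryModel:
    """Ligand-vs-metal accumulation model over a per-ROI measurement table.

    Parameters
    ----------
    data : DataFrame
        Tidy per-ROI table with columns ``compartment``,
        ``concentration`` (μM), ``q``, ``x`` and optionally ``sigma_q``,
        ``sigma_x``, ``sample_id``, ``roi_id``.
    compartments : sequence of str, optional
        Restrict the fit to these compartments (default: all present).

    Examples
    --------
    >>> model = StoichiometryModel(per_roi_table)        # doctest: +SKIP
    >>> res = model.fit(weighting="inverse-variance")    # doctest: +SKIP
    >>> print(res.summary())                             # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame,
                 compartments: Sequence[str] | None = None):
        for col in _MEASUREMENT_COLUMNS:
            if col not in data.columns:
                raise ValueError(f"measurement table lacks column {col!r}")
        self.data = data.copy()
        self.compartments = list(compartments) if compartments is not None else \
            sorted(self.data["compartment"].unique())
        missing = [c for c in self.compartments
                   if c not in set(self.data["compartment"])]
        if missing:
            raise ValueError(f"compartments absent from data: {missing}")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "StoichiometryModel":
        return cls(data, **kwargs)

    def fit(self, weighting: str = "none") -> "StoichiometryResults":
        curves = {}
        fits = {}
        for comp in self.compartments:
            curve = build_curve(self.data, comp)
            curves[comp] = curve
            fits[comp] = fit_slope(curve, weighting=weighting)
        return StoichiometryResults(self, curves, fits, weighting)


class StoichiometryResults:
    """Fitted per-compartment stoichiometry curves and their slopes."""

    def __init__(self, model: StoichiometryModel,
                 curves: Mapping[str, StoichiometryCurve],
                 fits: Mapping[str, SlopeFit], weighting: str):
        self.model = model
        self.curves = dict(curves)
        self.fits = dict(fits)
        self.weighting = weighting

    @property
    def params(self) -> pd.DataFrame:
        rows = []
        for comp, f in self.fits.items():
            rows.append({
                "compartment": comp, "slope": f.slope, "slope_se": f.slope_se,
                "intercept": f.intercept, "intercept_se": f.intercept_se,
                "origin_slope": f.origin_slope,
                "origin_slope_se": f.origin_slope_se,
                "n_points": f.n_points,
            })
        return pd.DataFrame(rows).set_index("compartment")

    def calibrate(self, rsf_pt: float | None = None,
                  rsf_cn: float | None = None,
                  use_origin_slope: bool = False) -> pd.DataFrame:
        """Per-compartment calibrated N:Pt atom ratios (needs RSFs)."""
        rows = []
        for comp, f in self.fits.items():
            slope = f.origin_slope if use_origin_slope else f.slope
            se = f.origin_slope_se if use_origin_slope else f.slope_se
            cal = calibrate_stoichiometry(slope, rsf_pt, rsf_cn, slope_se=se)
            rows.append({"compartment": comp, "n_per_pt": cal.ratio,
                         "n_per_pt_se": cal.ratio_se,
                         "calibrated": cal.calibrated, "slope": cal.slope})
        return pd.DataFrame(rows).set_index("compartment")

    def summary(self) -> str:
        """Text table of per-compartment slope estimates."""
        lines = [
            "Stoichiometry curve fits (label fraction x vs. Pt/N index q)",
            f"weighting: {self.weighting}",
            f"{'compartment':<12}{'n':>4}{'slope':>12}{'SE':>11}"
            f"{'intercept':>13}{'SE':>11}{'origin slope':>14}",
        ]
        for comp, f in self.fits.items():
            lines.append(
                f"{comp:<12}{f.n_points:>4}{f.slope:>12.5g}{f.slope_se:>11.3g}"
                f"{f.intercept:>13.4g}{f.intercept_se:>11.3g}{f.origin_slope:>14.5g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Label fraction (per mil) against Pt/N index per compartment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for comp, curve in self.curves.items():
            frame = curve.as_frame()
            ax.errorbar(frame["q"], 1000 * frame["x"],
                        yerr=1000 * frame["x_sd"], xerr=frame["q_sd"],
                        marker="o", linestyle="-", capsize=2, label=comp)
        ax.set_xlabel("Pt/N index q")
        ax.set_ylabel("label fraction x (per mil)")
        ax.legend()
        return ax
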