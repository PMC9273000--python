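"""Compartment masks and region-of-interest count extraction.

ROIs mirror the manual delineation practice for resin-section ion images:
each positive integer in the label image is one ROI, and a legend maps it
to a compartment name (cytoplasm, nucleus, nucleolus, chromatin,
aggregate, or a free-form id).  The nucleus label excludes nucleolus
pixels — compartments are mutually exclusive by construction.  Ratios are
always formed from ROI-summed counts, never from means of per-pixel
ratios, which are undefined at zero counts and bias-prone at low counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path

import numpy as np
import tifffile

from .channels import ChannelSpec
from .errors import DimensionMismatchError, UndefinedRatioError
from .io import AcquisitionStack

#: Canonical compartment names, in label order used by the phantom.
COMPARTMENTS = ("background", "cytoplasm", "nucleus", "nucleolus",
                "chromatin", "aggregate")


@dataclass
class CompartmentMask:
    """Label image assigning every pixel to exactly one ROI.

    Parameters
    ----------
    labels : ndarray of int
        Same dimensions as the stacks it applies to; 0 is background.
    legend : dict
        label value -> compartment name.  Several labels may share a
        compartment name (e.g. each cell's nucleolus is its own ROI).
    roi_ids : dict, optional
        label value -> free-form ROI id; defaults to
        ``"roi<label>_<compartment>"``.
    """

    labels: np.ndarray
    legend: dict[int, str]
    roi_ids: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels without legend entry: {sorted(unknown)}")
        for lab in present:
            self.roi_ids.setdefault(int(lab), f"roi{lab}_{self.legend[int(lab)]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def compartment_pixels(self, name: str) -> np.ndarray:
        """Boolean mask of all pixels whose ROI belongs to ``name``."""
        labs = [lab for lab, comp in self.legend.items() if comp == name]
        return np.isin(self.labels, labs)

    def shifted(self, d_row: int, d_col: int) -> "CompartmentMask":
        """Mask translated by whole pixels, background-filled at borders."""
        out = np.zeros_like(self.labels)
        rows, cols = self.labels.shape
        src_r = slice(max(0, -d_row), min(rows, rows - d_row))
        src_c = slice(max(0, -d_col), min(cols, cols - d_col))
        dst_r = slice(max(0, d_row), min(rows, rows + d_row))
        dst_c = slice(max(0, d_col), min(cols, cols + d_col))
        out[dst_r, dst_c] = self.labels[src_r, src_c]
        return CompartmentMask(out, dict(self.legend), dict(self.roi_ids))


def write_mask(mask: CompartmentMask, image_path: str, legend_path: str | None = None):
    """Persist a mask as a single-page label TIFF plus JSON legend."""
    image_path = Path(image_path)
    tifffile.imwrite(image_path, mask.labels.astype(np.int32))
    legend_path = Path(legend_path or image_path.with_suffix(".json"))
    legend_path.write_text(json.dumps(
        {"legend": {str(k): v for k, v in mask.legend.items()},
         "roi_ids": {str(k): v for k, v in mask.roi_ids.items()}}, indent=1))


def read_mask(image_path: str, legend_path: str | None = None) -> CompartmentMask:
    image_path = Path(image_path)
    labels = np.asarray(tifffile.imread(image_path)).astype(np.int64)
    legend_path = Path(legend_path or image_path.with_suffix(".json"))
    meta = json.loads(legend_path.read_text())
    legend = {int(k): v for k, v in meta["legend"].items()}
    roi_ids = {int(k): v for k, v in meta.get("roi_ids", {}).items()}
    return CompartmentMask(labels, legend, roi_ids)


@dataclass
class RoiChannelCounts:
    """Per-ROI summed counts for every channel of one stack."""

    roi_id: str
    compartment: str
    pixel_count: int
    counts: dict[str, int]          # species_label -> summed counts
    channels: dict[str, ChannelSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be ≥ 1")
        for lbl, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative summed counts for {lbl}")


def extract_roi_counts(stack: AcquisitionStack,
                       mask: CompartmentMask) -> list[RoiChannelCounts]:
    """Sum each channel's counts over every non-background ROI.

    Conservation holds exactly: the per-channel sums over all ROIs plus
    the background sum equal the image total.  ROIs with zero pixels are
    omitted with a warning.
    """
    if mask.shape != stack.shape:
        raise DimensionMismatchError(
            f"mask dims {mask.shape} != stack dims {stack.shape}")
    labels = mask.labels.ravel()
    n_bins = int(labels.max()) + 1 if labels.size else 1
    pix_per = np.bincount(labels, minlength=n_bins)
    sums = {
        lbl: np.bincount(labels, weights=m.counts.ravel().astype(np.float64),
                         minlength=n_bins).astype(np.int64)
        for lbl, m in stack.maps.items()
    }
    out: list[RoiChannelCounts] = []
    for lab in sorted(mask.legend):
        if lab == 0:
            continue
        if lab >= n_bins or pix_per[lab] == 0:
            warnings.warn(f"ROI label {lab} ({mask.legend[lab]}) has zero pixels; omitted")
            continue
        out.append(RoiChannelCounts(
            roi_id=mask.roi_ids[lab],
            compartment=mask.legend[lab],
            pixel_count=int(pix_per[lab]),
            counts={lbl: int(s[lab]) for lbl, s in sums.items()},
            channels={lbl: m.channel for lbl, m in stack.maps.items()},
        ))
    return out


@dataclass
class CountRatio:
    """A reference-normalised signal with first-order counting error.

    ``sigma = value * sqrt(1/n_num + 1/n_ref)`` for independent Poisson
    counts.  A zero numerator yields ``value = 0`` with a one-sided upper
    bound ``sigma = 1/n_ref`` (the scale of a single-count fluctuation),
    flagged by ``upper_bound_only``.
    """

    value: float
    sigma: float
    n_num: int
    n_ref: int
    upper_bound_only: bool = False


def normalized_signal(roi: RoiChannelCounts, numerator: str,
                      reference: str = "12C2") -> CountRatio:
    """Ratio of one channel's ROI sum to a reference channel's ROI sum.

    Parameters
    ----------
    roi : RoiChannelCounts
    numerator, reference : str
        species labels present in ``roi.counts``; the reference sum must
        be positive.
    """
    n_num = roi.counts[numerator]
    n_ref = roi.counts[reference]
    return poisson_ratio(n_num, n_ref)


def poisson_ratio(n_num: int, n_ref: int) -> CountRatio:
    """Counting-error-propagated ratio of two independent Poisson counts."""
    if n_ref <= 0:
        raise UndefinedRatioError("reference counts are zero; ratio undefined")
    if n_num == 0:
        return CountRatio(0.0, 1.0 / n_ref, 0, n_ref, upper_bound_only=True)
    r = n_num / n_ref
    return CountRatio(r, r * sqrt(1.0 / n_num + 1.0 / n_ref), n_num, n_ref)
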