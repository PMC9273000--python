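"""Translation registration of sequentially acquired runs.

The platinum and nitrogen-isotope measurements of one field are acquired
sequentially, so the two frames can be displaced by stage drift.  A
translation-only model is used (successive frames of the same field do
not rotate or scale), estimated by phase correlation on the ¹²C₂⁻
channel — the structural reference present in both runs; drug channels
are never used because platinum can be absent in controls.

Counts are realigned by whole pixels with zero-fill at exposed borders;
the sub-pixel residual is recorded in metadata but never resampled, since
interpolation would destroy the integer Poisson statistics the counting
error model relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .errors import ConfigurationError, NoStructureError
from .io import AcquisitionStack, IonCountMap


@dataclass(frozen=True)
class Shift:
    """Displacement of the moving frame relative to the reference frame.

    ``moving ≈ translate(ref, (d_row, d_col))``: positive ``d_row`` means
    the moving frame's content sits ``d_row`` pixels lower.  ``score`` is
    the Pearson correlation between the reference and the realigned
    moving frame on their overlap.
    """

    d_row: float
    d_col: float
    score: float = float("nan")

    @property
    def integer(self) -> tuple[int, int]:
        return (int(round(self.d_row)), int(round(self.d_col)))

    @property
    def subpixel_residual(self) -> tuple[float, float]:
        ir, ic = self.integer
        return (self.d_row - ir, self.d_col - ic)

    def inverse(self) -> "Shift":
        return Shift(-self.d_row, -self.d_col, self.score)


def _translate(arr: np.ndarray, d_row: int, d_col: int) -> np.ndarray:
    """Whole-pixel translation with zero-fill; counts stay integers."""
    out = np.zeros_like(arr)
    rows, cols = arr.shape
    src_r = slice(max(0, -d_row), min(rows, rows - d_row))
    src_c = slice(max(0, -d_col), min(cols, cols - d_col))
    dst_r = slice(max(0, d_row), min(rows, rows + d_row))
    dst_c = slice(max(0, d_col), min(cols, cols + d_col))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def _overlap_correlation(ref: np.ndarray, aligned: np.ndarray,
                         d_row: int, d_col: int) -> float:
    rows, cols = ref.shape
    r_sl = slice(max(0, d_row), min(rows, rows + d_row))
    c_sl = slice(max(0, d_col), min(cols, cols + d_col))
    a = ref[r_sl, c_sl].astype(np.float64).ravel()
    b = aligned[r_sl, c_sl].astype(np.float64).ravel()
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def estimate_shift(ref: IonCountMap, moving: IonCountMap,
                   max_shift: int = 20, upsample_factor: int = 10) -> Shift:
    """Phase-correlation estimate of the moving frame's displacement.

    Deterministic for fixed inputs.  ``upsample_factor > 1`` adds
    sub-pixel refinement by upsampled cross-correlation; the integer part
    is what :func:`apply_shift` uses.

    Raises
    ------
    NoStructureError
        If either image is flat (zero variance).
    ConfigurationError
        If the estimate exceeds ``max_shift`` pixels on either axis.
    """
    a = ref.counts.astype(np.float64)
    b = moving.counts.astype(np.float64)
    if a.shape != b.shape:
        raise ConfigurationError("maps must share dimensions")
    if a.std() == 0 or b.std() == 0:
        raise NoStructureError("flat image: cannot estimate a shift")
    # phase_cross_correlation returns the shift that registers the moving
    # image onto the reference; our convention is the displacement of the
    # moving frame, i.e. its negation.
    reg_shift, _, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample_factor, normalization="phase")
    d_row, d_col = (-float(reg_shift[0]), -float(reg_shift[1]))
    if abs(d_row) > max_shift or abs(d_col) > max_shift:
        raise ConfigurationError(
            f"estimated shift ({d_row:.2f}, {d_col:.2f}) exceeds max_shift={max_shift}")
    ir, ic = int(round(d_row)), int(round(d_col))
    aligned = _translate(moving.counts, -ir, -ic)
    score = _overlap_correlation(ref.counts, aligned, -ir, -ic)
    return Shift(d_row, d_col, score)


def estimate_stack_shift(ref_stack: AcquisitionStack,
                         moving_stack: AcquisitionStack,
                         structural_channel: str = "12C2",
                         max_shift: int = 20) -> Shift:
    """Shift between two runs, estimated on the shared structural channel."""
    return estimate_shift(ref_stack.channel(structural_channel),
                          moving_stack.channel(structural_channel),
                          max_shift=max_shift)


def apply_shift(stack: AcquisitionStack, shift: Shift) -> AcquisitionStack:
    """Translate every channel by the integer part of ``shift``.

    Zero-fills exposed borders and records the number of zero-filled
    pixels and the sub-pixel residual in the stack metadata.
    """
    ir, ic = shift.integer
    rows, cols = stack.shape
    new_counts = {lbl: _translate(m.counts, ir, ic)
                  for lbl, m in stack.maps.items()}
    out = stack.with_counts(new_counts)
    filled = rows * cols - (rows - abs(ir)) * (cols - abs(ic))
    out.metadata.update({
        "applied_shift": (ir, ic),
        "subpixel_residual": shift.subpixel_residual,
        "zero_filled_pixels": int(filled),
    })
    return out


def register_n_run(pt_stack: AcquisitionStack, n_stack: AcquisitionStack,
                   max_shift: int = 20) -> tuple[AcquisitionStack, Shift]:
    """Align the nitrogen run onto the platinum run's frame.

    Returns the realigned nitrogen stack and the estimated shift (the
    displacement of the nitrogen frame before realignment).
    """
    shift = estimate_stack_shift(pt_stack, n_stack, max_shift=max_shift)
    aligned = apply_shift(n_stack, shift.inverse())
    return aligned, shift
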