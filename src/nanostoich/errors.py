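"""Structured exceptions raised by the analysis stages.

Every stage failure carries enough context (channel name, pixel
coordinates, stage) that a pipeline log entry is self-explanatory.
"""


class NanostoichError(Exception):
    """Base class for all package errors."""


class MissingChannelError(NanostoichError):
    """A required secondary-ion channel is absent from a stack."""

    def __init__(self, species_label: str, run_type: str | None = None):
        self.species_label = species_label
        self.run_type = run_type
        msg = f"missing channel {species_label}"
        if run_type:
            msg += f" (required for run_type {run_type})"
        super().__init__(msg)


class InvalidCountsError(NanostoichError):
    """Pixel values that are not non-negative integers.

    Carries the offending (row, col) coordinates so bad conversions of
    accumulated-frame data can be located; counts are never silently
    rounded because the Poisson error model is only valid on raw counts.
    """

    def __init__(self, channel: str, coordinates):
        self.channel = channel
        self.coordinates = list(coordinates)
        shown = ", ".join(str(c) for c in self.coordinates[:5])
        more = "" if len(self.coordinates) <= 5 else ", ..."
        super().__init__(
            f"channel {channel}: non-integer or negative counts at pixels [{shown}{more}]"
        )


class DimensionMismatchError(NanostoichError):
    """Mask or map dimensions do not match the stack."""


class UndefinedRatioError(NanostoichError):
    """A count ratio with a zero-count reference or denominator."""


class DegenerateVarianceError(NanostoichError):
    """A group comparison with zero pooled variance."""


class NoStructureError(NanostoichError):
    """Registration attempted on a flat (zero-variance) image."""


class UnderdeterminedFitError(NanostoichError):
    """Slope fit requested with fewer than two distinct abscissa values."""


class ConfigurationError(NanostoichError):
    """Invalid run or phantom configuration."""


class StageError(NanostoichError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
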