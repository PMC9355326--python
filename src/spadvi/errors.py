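"""Exception hierarchy for the spadvi pipeline.

Each pipeline stage raises a dedicated subclass so that orchestration code
(and the CLI) can map failures to stage-named exit codes.
"""


class SpadviError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(SpadviError):
    """Invalid or non-finite configuration values."""

    exit_code = 2


class GeometryError(SpadviError):
    """Scene geometry cannot accommodate the requested panel and plant."""

    exit_code = 3


class ShapeError(SpadviError):
    """Array shape or channel-count mismatch."""

    exit_code = 4


class BandError(SpadviError):
    """A required spectral band is missing or unknown."""

    exit_code = 5


class DegenerateInputError(SpadviError):
    """Input carries no usable variation (constant image, zero variance)."""

    exit_code = 6


class SegmentationError(SpadviError):
    """Thresholding produced an all-plant or all-background mask."""

    exit_code = 7


class EmptyMaskError(SpadviError):
    """A plant mask with no foreground pixels was supplied."""

    exit_code = 8


class CorrectionError(SpadviError):
    """White-panel correction impossible (non-positive panel signal)."""

    exit_code = 9


class ScreeningError(SpadviError):
    """Feature screening eliminated every candidate column."""

    exit_code = 10


class DesignError(SpadviError):
    """Rank-deficient or otherwise unusable regression design."""

    exit_code = 11


class IOStageError(SpadviError):
    """Missing manifest / dataset files."""

    exit_code = 12
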