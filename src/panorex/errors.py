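"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: :class:`InputError` (and subclasses) -> 2,
:class:`SegmentationEmptyError` -> 3, optimizer non-convergence -> 4.
"""


class PanorexError(Exception):
    """Base class for all package errors."""


class InputError(PanorexError):
    """Unreadable, malformed or unsupported input."""


class AmbiguousSeriesError(InputError):
    """A DICOM directory mixes more than one series."""


class FormatError(InputError):
    """A packed volume file is malformed or truncated."""


class ConfigError(PanorexError):
    """Invalid configuration value or unknown configuration key."""


class SegmentationEmptyError(PanorexError):
    """No voxel survived the enamel threshold; check threshold/units."""


class DegenerateCurveError(PanorexError):
    """A curve whose derivative vanishes everywhere has no normals."""
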