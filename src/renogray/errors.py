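"""Exception hierarchy shared across the package.

All domain errors derive from :class:`RenoGrayError` so the CLI can map
them onto exit codes (2 for usage/configuration, 3 for data problems).
"""


class RenoGrayError(Exception):
    """Base class for all errors raised by renogray."""


class FormatError(RenoGrayError):
    """An input file is syntactically valid but in an unsupported format
    (e.g. a BMP bit depth the tool does not read)."""


class ValidationError(RenoGrayError):
    """An input violates a documented contract (bad label, bad column,
    mismatched dimensions, out-of-range value)."""


class ConfigurationError(RenoGrayError):
    """The tool configuration is inconsistent (e.g. brightness ranges that
    do not tile [0, 255])."""


class EmptyRegionError(RenoGrayError):
    """A region of interest contains no pixels."""


class DegenerateFasciaError(RenoGrayError):
    """The fascia reference region has gray-scale median 0 (or the region
    is otherwise unusable as a normalization anchor)."""


class DegenerateSampleError(RenoGrayError):
    """A statistical sample is degenerate (zero variance or too small)."""


class InsufficientGroupsError(RenoGrayError):
    """Fewer than two groups are available for a between-group comparison."""
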