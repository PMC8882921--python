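"""Exception hierarchy shared across the package."""


class MicrostateError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MicrostateError, ValueError):
    """Input violates a precondition (shape, channel mismatch, NaN, range)."""


class DegenerateMapError(MicrostateError, ValueError):
    """A topography has zero variance where a metric requires variance."""


class DegenerateClusteringError(MicrostateError, ValueError):
    """All candidate maps coincide (up to sign) yet K >= 2 was requested."""


class ConfigError(MicrostateError, ValueError):
    """A configuration value is out of its admissible range."""


class NoSplitError(MicrostateError, ValueError):
    """Ratings cannot be binarized (all values identical)."""


class FormatError(MicrostateError, ValueError):
    """A file on disk does not match the expected on-disk format."""
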