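"""Exception hierarchy.

Every error raised by the library derives from :class:`MsplsError` so that
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class MsplsError(Exception):
    """Base class for all mspls errors."""


class ConfigurationError(MsplsError):
    """An invalid configuration value; the message names the field."""


class DataError(MsplsError):
    """Invalid or incomplete input data."""


class SchemaError(DataError):
    """A table does not match the canonical column schema."""


class DimensionError(MsplsError):
    """Mismatched array dimensions."""


class DegenerateSkeletonError(MsplsError):
    """No skeleton voxel survives the FA threshold."""


class EmptyRegionError(MsplsError):
    """A regional summary was requested over an empty voxel set."""


class RankError(MsplsError):
    """More PLS components requested than the predictor matrix supports."""


class DegenerateOutcomeError(MsplsError):
    """The outcome vector carries no variance."""


class ParameterError(MsplsError):
    """An invalid scalar parameter (e.g. a non-positive normative SD)."""
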