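"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`NirsnetError` so callers can catch
pipeline failures distinctly from programming errors.
"""


class NirsnetError(Exception):
    """Base class for all pipeline errors."""


class MontageError(NirsnetError):
    """Invalid montage definition (duplicate channels, bad separation, ...)."""


class FormatError(NirsnetError):
    """A file could not be parsed as the declared format."""


class ChannelMismatchError(FormatError):
    """Channels in a recording do not match the montage."""


class ConfigError(NirsnetError):
    """Invalid pipeline configuration."""


class DesignError(NirsnetError):
    """Invalid block design or design matrix."""


class FixtureError(NirsnetError):
    """A packaged fixture is missing or corrupted."""


class CovarianceError(NirsnetError):
    """A requested latent correlation structure is infeasible."""


class PreprocessError(NirsnetError):
    """Artifact repair or filtering cannot proceed."""


class StatsError(NirsnetError):
    """A statistical test is undefined for the given data."""
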