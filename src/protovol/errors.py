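"""Exception hierarchy.

Every error raised by this package derives from :class:`ProtovolError` so
callers can catch the package's failures without masking programming errors.
"""


class ProtovolError(Exception):
    """Base class for all protovol errors."""


class ConfigurationError(ProtovolError):
    """A spec/config object is internally inconsistent or unusable."""


class DataError(ProtovolError):
    """Input data violates the documented contract (bad label, duplicate id...)."""


class FormatError(ProtovolError):
    """A file on disk does not parse as the expected format."""


class EpisodeError(ProtovolError):
    """An episode cannot be sampled from the given pool."""


class UndefinedMetricError(ProtovolError):
    """A metric is mathematically undefined for the given inputs."""
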