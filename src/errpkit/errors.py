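"""Exception hierarchy.

Every error raised by errpkit derives from :class:`ErrpKitError` so callers
can catch the package's failures without catching programming errors.
"""


class ErrpKitError(Exception):
    """Base class for all errpkit errors."""


class ConfigError(ErrpKitError, ValueError):
    """Invalid configuration value (band edges, windows, search space...)."""


class UnsupportedFormatError(ErrpKitError, ValueError):
    """File format not recognised by a reader."""


class UnknownMarkerError(ErrpKitError, KeyError):
    """Marker description absent from the event-code map in strict mode."""


class CorruptStoreError(ErrpKitError, IOError):
    """Epoch store sidecar and array container disagree."""


class EmptyEpochsError(ErrpKitError, ValueError):
    """Epoching produced no usable trials."""


class EmptyClassError(ErrpKitError, ValueError):
    """An operation requiring both trial classes found one empty."""


class DimensionError(ErrpKitError, ValueError):
    """Requested spatial-filter dimension exceeds the channel count."""


class ReferenceError_(ErrpKitError, ValueError):
    """Average reference needs at least two channels."""


class ChannelMismatchError(ErrpKitError, KeyError):
    """A channel required by a model is missing from the data."""


class DegenerateFeaturesError(ErrpKitError, ValueError):
    """All candidate features had zero variance on the training set."""


class StratificationError(ErrpKitError, ValueError):
    """A cross-validation fold would be missing one of the classes."""


class RegionMissingError(ErrpKitError, KeyError):
    """A screening criterion refers to a channel region with no channels."""


class UndefinedCorrelationError(ErrpKitError, ValueError):
    """Pearson correlation undefined because one input has zero variance."""
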