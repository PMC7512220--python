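"""Exception and warning hierarchy.

Every error raised by the package derives from :class:`SwathError` so callers
(and the CLI, which maps each class to a distinct exit code) can catch them
uniformly.
"""


class SwathError(Exception):
    """Base class for all swathms errors."""


class ConfigurationError(SwathError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ReferentialIntegrityError(SwathError, KeyError):
    """A record refers to an identifier absent from the metadata tables."""


class DegenerateRunError(SwathError, ValueError):
    """A run (column) is degenerate, e.g. has zero total intensity."""


class DegenerateClusteringError(SwathError, ValueError):
    """Clustering is undefined, e.g. all score coordinates identical."""


class StageError(SwathError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


class UndefinedFoldChangeWarning(UserWarning):
    """A protein's fold change is undefined (non-positive or non-finite mean)."""


class ZeroIntensityWarning(UserWarning):
    """A protein had no observed fragments in some run; value set to 0."""


class ZeroVarianceWarning(UserWarning):
    """A zero-variance protein was dropped from a scaling/PCA step."""


class UnstableClusteringWarning(UserWarning):
    """The two-cluster partition is weakly supported (low silhouette)."""
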