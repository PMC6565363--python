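"""Exception hierarchy for socialsv.

Every error raised deliberately by the package derives from
:class:`SocialSVError`, so callers can catch pipeline failures without
masking programming errors.
"""


class SocialSVError(Exception):
    """Base class for all socialsv errors."""


class InvalidParameterError(SocialSVError, ValueError):
    """A model parameter violates its domain (e.g. k <= 0, beta < 0)."""


class InsufficientDataError(SocialSVError, ValueError):
    """Not enough usable trials/subjects for the requested computation."""


class IncompleteGridError(SocialSVError, ValueError):
    """Model selection requested with variants missing for some subject."""


class InvalidRequestError(SocialSVError, ValueError):
    """A request that is undefined under the given configuration
    (e.g. offline values under a shared-parameter variant)."""


class DegenerateSplitError(SocialSVError, ValueError):
    """Median split is undefined because all values are identical."""


class DegenerateInputError(SocialSVError, ValueError):
    """Degenerate numerical input (constant column, zero variance...)."""


class InfeasibleDesignError(SocialSVError, RuntimeError):
    """Trial-set search exhausted its iteration budget.

    Carries the best candidate diagnostics achieved so the caller can see
    how far the search got.
    """

    def __init__(self, message: str, best: dict | None = None):
        super().__init__(message)
        self.best = best or {}


class UntrainableError(SocialSVError, RuntimeError):
    """A classifier training set has a single label after downsampling."""


class ConfigError(SocialSVError, ValueError):
    """Pipeline configuration failed schema validation; names the field."""

    def __init__(self, field: str, message: str):
        super().__init__(f"config field '{field}': {message}")
        self.field = field
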