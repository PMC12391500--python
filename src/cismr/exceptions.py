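"""Exception hierarchy.

Every fatal condition in the pipeline raises a subclass of :class:`CisMRError`
so that callers (and the CLI) can distinguish analysis failures from bugs.
"""


class CisMRError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(CisMRError):
    """Invalid or missing configuration: bad column map, wrong trait scale,
    missing file, threshold out of range."""


class EmptyResultError(CisMRError):
    """A pipeline stage produced zero records.

    Carries the name of the stage that emptied the data so that a failed run
    names the filter responsible.
    """

    def __init__(self, stage: str, detail: str = ""):
        self.stage = stage
        msg = f"stage '{stage}' produced an empty result"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class HarmonisationError(CisMRError):
    """Inputs that should share a common allele orientation do not."""


class EstimationError(CisMRError):
    """An estimator's preconditions are violated (e.g. zero exposure beta,
    too few variants, all variants flagged as outliers)."""
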