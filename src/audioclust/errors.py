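"""Exception hierarchy for audioclust.

Every error raised by the package derives from :class:`AudioclustError`,
so callers (and the CLI) can catch one type at the boundary.
"""


class AudioclustError(Exception):
    """Base class for all audioclust errors."""


class FormatError(AudioclustError):
    """A file does not follow the documented column dialect or schema."""


class ParseError(AudioclustError):
    """A cell could not be parsed (non-numeric threshold, bad token)."""


class ValidationError(AudioclustError):
    """A parsed value violates a domain invariant (range, uniqueness)."""


class ContractError(AudioclustError):
    """An operation was called with arguments violating its contract."""


class DegenerateDataError(AudioclustError):
    """The data is too degenerate for the requested computation
    (zero variance, fewer distinct points than clusters, ...)."""


class ModelFormatError(AudioclustError):
    """A persisted cluster model violates the model JSON schema."""


class FittingError(AudioclustError):
    """A regression fit failed (rank deficiency, separation)."""


class ConvergenceError(FittingError):
    """An iterative fit did not converge within its iteration budget."""


class GeneratorError(AudioclustError):
    """A simulation configuration cannot produce a valid cohort."""
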