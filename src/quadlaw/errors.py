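"""Exception hierarchy.

Every error raised by quadlaw derives from :class:`QuadlawError`, so callers
can catch one type; the CLI maps the subclasses onto distinct exit codes.
"""


class QuadlawError(Exception):
    """Base class for all quadlaw errors."""


class FormatError(QuadlawError):
    """A file does not conform to the expected delimited-text layout."""


class ConflictError(FormatError):
    """Duplicate records disagree about the same (L-quadrat, S-quadrat, species) cell."""


class DesignError(QuadlawError):
    """Survey geometry is inconsistent (ragged S-quadrat counts, too few quadrats)."""


class DomainError(QuadlawError):
    """A value lies outside its mathematical domain (e.g. p outside [0, 1])."""


class UndefinedTransformError(DomainError):
    """The log transform is undefined for this species (p in {0,1} or zero variance)."""


class FitError(QuadlawError):
    """The regression cannot be fitted (too few points or degenerate abscissa)."""


class AnalysisError(QuadlawError):
    """The end-to-end analysis cannot proceed (e.g. fewer than 3 includable species)."""


class ConfigError(QuadlawError):
    """Invalid run configuration or simulation specification."""
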