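"""Exception hierarchy.

Every error raised by the package derives from :class:`ComposkernError`
so callers (and the CLI) can catch failures uniformly while still
distinguishing the cause.
"""


class ComposkernError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ComposkernError, ValueError):
    """A value violates a documented precondition."""


class DegeneratePerturbationError(ComposkernError, ValueError):
    """A simplex perturbation is undefined at the requested point."""


class ZeroHandlingError(ComposkernError, ValueError):
    """A log-ratio operation hit a zero entry without a positive shift."""


class SchemaError(ComposkernError, ValueError):
    """Tabular input does not match the expected schema (labels, columns)."""


class LabelMismatchError(SchemaError):
    """Component labels do not line up between two objects."""


class InvalidTreeError(ComposkernError, ValueError):
    """A phylogenetic tree is unusable (e.g. missing branch lengths)."""


class InvalidPartitionError(ComposkernError, ValueError):
    """Blocks do not form a disjoint, exhaustive partition."""


class NumericalError(ComposkernError, ArithmeticError):
    """A linear solve or decomposition failed beyond tolerance."""


class SelectionFailureError(ComposkernError, RuntimeError):
    """Every candidate kernel failed during model selection."""


class UndefinedMetricError(ComposkernError, ValueError):
    """A score is undefined for the given inputs (e.g. absent class)."""
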