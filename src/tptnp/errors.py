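"""Exception hierarchy for the pipeline."""


class TptnpError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(TptnpError):
    """Input table is missing a required column or has a malformed row."""


class EmptyInputError(TptnpError):
    """Input table or query contains no usable data."""


class UsageError(TptnpError):
    """Caller supplied an invalid parameter (unknown format, bad fraction...)."""


class InvalidCodeError(TptnpError):
    """ATC code does not start with a valid anatomical main-group letter."""


class LookupError_(TptnpError):
    """A requested identifier is absent from the object queried."""


class TestInfeasibleError(TptnpError):
    """Contingency table is degenerate; the chi-square test is undefined."""


class DegenerateModuleError(TptnpError):
    """Module has fewer than two targets; centrality ranking is undefined."""


class ConvergenceError(TptnpError):
    """Iterative solver (eigenvector power iteration) failed to converge."""
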