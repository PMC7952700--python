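"""Exception hierarchy shared across the pipeline stages."""


class PryntError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PryntError):
    """An input file does not conform to its expected tabular layout."""


class EmptySeedError(PryntError):
    """No deregulated protein could be placed in the network / mapping."""


class EmptyNetworkError(PryntError):
    """Filtering left no interaction edges at all."""


class ConsistencyError(PryntError):
    """Two artifacts that must describe the same objects disagree."""


class ConvergenceError(PryntError):
    """The random-walk iteration did not reach the tolerance in time."""

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None) -> None:
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class SyntheticSpecError(PryntError):
    """A synthetic-study specification is infeasible or out of range."""
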