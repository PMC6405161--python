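"""Exception hierarchy.

Validation problems (bad matrices, bad indices, bad parameters) and
numerical failures (non-convergence, integration breakdown) are kept in
separate branches so callers -- and the command line -- can map them to
distinct exit statuses.
"""


class IctalnetError(Exception):
    """Base class for all package errors."""


class ValidationError(IctalnetError):
    """Invalid input data or parameters."""


class NonSquareMatrixError(ValidationError):
    pass


class NonFiniteWeightError(ValidationError):
    pass


class NegativeWeightError(ValidationError):
    pass


class LabelCountError(ValidationError):
    pass


class ZeroMatrixError(ValidationError):
    """An all-zero connectome cannot be normalized."""


class EdgeIndexError(ValidationError):
    """Self-edge or out-of-range node index in an edge operation."""


class NumericalError(IctalnetError):
    """A numerical procedure failed; never a silent wrong answer."""


class ConvergenceError(NumericalError):
    """Root solver did not converge within its iteration budget."""


class SimulationError(NumericalError):
    """ODE integration failed (step-size collapse or non-finite state)."""
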