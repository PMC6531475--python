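"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage errors -> 1, :class:`DataError`
-> 2, :class:`SolverError` -> 3.
"""


class MSMDenoiseError(Exception):
    """Base class for all package errors."""


class DataError(MSMDenoiseError):
    """Invalid input data: bad shapes, ranges, unreadable files."""


class SolverError(MSMDenoiseError):
    """Numerical failure of the linear solver.

    Carries the relative residual reached when the iteration stopped.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
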