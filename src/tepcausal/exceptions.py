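"""Exception hierarchy for tepcausal.

All errors raised by the library derive from :class:`TepError` so callers
can catch the package's failures with a single except clause.
"""

from __future__ import annotations


class TepError(Exception):
    """Base class for all tepcausal errors."""


class InsufficientPointsError(TepError, ValueError):
    """A series or attractor has too few points for the requested operation."""


class ConstantSeriesError(TepError, ValueError):
    """A zero-variance series cannot be standardized."""


class DegenerateReferencePairError(TepError, ValueError):
    """The reference point pair used for the scale ratio has zero distance."""

    def __init__(self, which: str, i: int, j: int):
        self.which = which
        self.indices = (i, j)
        super().__init__(
            f"degenerate reference pair: distance between points {i} and {j} "
            f"on the {which} attractor is zero"
        )


class CoincidentPointsError(TepError, ValueError):
    """Two distinct points of the target attractor coincide, so a relative
    error denominator vanishes."""

    def __init__(self, i: int, j: int):
        self.indices = (i, j)
        super().__init__(
            f"coincident points on target attractor: points {i} and {j} "
            "are at zero distance (relative error undefined)"
        )


class DivergentTrajectoryError(TepError, ArithmeticError):
    """A simulated trajectory escaped to a non-finite value."""

    def __init__(self, step: int, variable: str | None = None):
        self.step = step
        self.variable = variable
        where = f" for variable {variable!r}" if variable else ""
        super().__init__(f"divergent trajectory at step {step}{where}")


class SingleClassTruthError(TepError, ValueError):
    """The ground truth contains only edges or only non-edges, so a ROC
    curve is undefined."""


class ParseError(TepError, ValueError):
    """A delimited input file violates the expected layout."""
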