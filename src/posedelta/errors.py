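"""Exception hierarchy."""


class PoseDeltaError(Exception):
    """Base class for all package errors."""


class ParseError(PoseDeltaError):
    """A structure or table file could not be parsed."""


class TopologyError(PoseDeltaError):
    """Atom bookkeeping is inconsistent (masks, parameters, counts)."""


class GeometryError(PoseDeltaError):
    """Coordinates violate a precondition (coincident atoms, degenerate fit)."""


class FitError(PoseDeltaError):
    """Nonlinear regression failed to converge."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual
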