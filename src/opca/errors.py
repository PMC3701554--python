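"""Exception types shared across the package."""


class OpcaError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(OpcaError, ValueError):
    """The input is degenerate for the requested operation.

    Examples: center of charge of a neutral set, 2-charge dipole
    construction for a zero-dipole distribution.
    """


class SingularityError(OpcaError, ValueError):
    """An evaluation point (numerically) coincides with a charge position."""


class ConventionError(OpcaError, ValueError):
    """Two moment objects use incompatible origins or conventions."""


class ConvergenceError(OpcaError, RuntimeError):
    """A numerical procedure failed to converge within its budget."""


class InfeasibleError(OpcaError, RuntimeError):
    """A constrained solve has no feasible point."""
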