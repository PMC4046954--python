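"""Exception types shared across the package."""


class LarvaforageError(Exception):
    """Base class for all package errors."""


class ValidationError(LarvaforageError):
    """A trait set, environment, or configuration violates an invariant."""


class ConfigParseError(LarvaforageError):
    """A configuration file could not be parsed."""


class ThermalToleranceError(LarvaforageError):
    """Ambient temperature exceeds the larva's upper thermal tolerance.

    Larvae encountering temperatures above x_tol are excluded from
    simulation rather than modelled with extrapolated physiology.
    """


class SolverError(LarvaforageError):
    """A root-finding or optimisation routine failed to bracket a solution."""
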