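"""Exception types shared across the simulator."""


class IrmsimError(Exception):
    """Base class for all irmsim errors."""


class InvalidInputError(IrmsimError, ValueError):
    """An argument is outside the admissible domain of an operation."""


class ConfigurationError(IrmsimError, ValueError):
    """A configuration object violates one of its invariants."""


class DegenerateCohortError(IrmsimError, RuntimeError):
    """A selection step produced an empty cohort (all exposed mosquitoes died,
    or there are no breeding parents at all)."""


class CohortExtinctSignal(IrmsimError, RuntimeError):
    """Raised inside the gonotrophic-cycle loop when no females remain; the
    caller truncates the cycle loop at the last non-empty cycle."""


class CalibrationError(IrmsimError, RuntimeError):
    """The exposure-scaling-factor calibration could not bracket its target."""
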