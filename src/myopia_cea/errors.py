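"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: configuration problems exit 2,
calibration non-convergence exits 3, violated model invariants exit 4.
"""


class MyopiaCEAError(Exception):
    """Base class for all package errors."""


class ValidationError(MyopiaCEAError, ValueError):
    """An input value violates a documented invariant."""


class ConfigurationError(MyopiaCEAError):
    """A parameter file or bundle is incomplete or malformed."""


class TerminalCycleError(MyopiaCEAError):
    """Attempt to advance a cohort past the final model age (18 years)."""


class CalibrationError(MyopiaCEAError):
    """Calibration could not reach its tolerances within budget."""


class InvariantError(MyopiaCEAError):
    """An internal consistency check failed (a bug, not a user error)."""
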