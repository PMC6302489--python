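"""Exception hierarchy shared across the package.

Validation problems (bad designs, malformed tables, inconsistent
parameters) raise :class:`ValidationError`; numerical failures during
fitting or power evaluation raise :class:`NumericalError`.  The CLI maps
these to exit codes 2 and 3 respectively.
"""


class PairPowerError(Exception):
    """Base class for all package errors."""


class ValidationError(PairPowerError, ValueError):
    """Invalid user input: designs, tables, parameters, file contents."""


class NumericalError(PairPowerError, RuntimeError):
    """A computation failed numerically (singular system, non-convergence)."""
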