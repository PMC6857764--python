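"""Exception hierarchy.

``InputError`` covers malformed or inconsistent user input (CLI exit code 2);
``NumericalError`` covers failures of the estimation machinery itself
(CLI exit code 3).
"""


class MethmrError(Exception):
    """Base class for all package errors."""


class InputError(MethmrError):
    """Malformed, missing or inconsistent input."""


class MatchingError(InputError):
    """No case-control pairs could be formed under the matching constraints."""


class DependencyError(InputError):
    """A pipeline stage was requested before its upstream artifacts exist."""


class NumericalError(MethmrError):
    """An estimation routine failed numerically."""


class NoInformationError(NumericalError):
    """A likelihood carries no information about the parameter of interest
    (e.g. every within-pair difference is zero)."""


class ConvergenceError(NumericalError):
    """An iterative fit diverged or hit its iteration cap; diagnostics are
    attached to the message."""
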