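"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code (see :mod:`overlapmodel.cli`).
"""


class OverlapModelError(Exception):
    """Base class for all package errors."""


class InputError(OverlapModelError):
    """Malformed or inconsistent user input (files, coordinates, terms)."""


class DegenerateNullError(OverlapModelError):
    """The mappable start domain G0(y) is empty: no valid start position
    exists for a query of the requested length, so the null distribution
    (uniform on G0(y)) is undefined."""


class IdentifiabilityError(OverlapModelError):
    """The requested model is not identifiable on the given reference
    geometry (the pattern design matrix is column-rank deficient), so the
    maximum-likelihood estimate is not unique."""


class ConvergenceError(OverlapModelError):
    """Maximum-likelihood estimation failed to converge (a coefficient is
    drifting to +/- infinity, typically because a sufficient statistic is
    zero or a nested pair of statistics is equal)."""
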