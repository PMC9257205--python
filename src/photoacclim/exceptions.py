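"""Package-specific exception types."""


class PhotoacclimError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PhotoacclimError, ValueError):
    """An argument violates a documented precondition."""


class NoSolutionError(PhotoacclimError):
    """A requested inversion has no physically admissible solution."""


class ConvergenceError(PhotoacclimError):
    """An iterative solver or optimizer failed to converge."""


class NotIdentifiableError(PhotoacclimError):
    """The requested parameters cannot be identified from the data given."""


class GridMismatchError(PhotoacclimError, ValueError):
    """Spectral inputs are not defined on a common wavelength grid."""
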