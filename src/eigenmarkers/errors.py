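"""Exception and warning types shared across the package."""


class EigenmarkersError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EigenmarkersError, ValueError):
    """A configuration or call parameter is outside its valid range."""


class DegenerateInputError(EigenmarkersError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero variance)."""


class AlignmentError(EigenmarkersError, ValueError):
    """Region labels or dimensions of two objects do not line up."""


class DisconnectedGraphError(EigenmarkersError, ValueError):
    """A graph that must be connected has more than one component."""


class ShortSeriesWarning(UserWarning):
    """The time series is too short to resolve a requested frequency."""


class DegenerateEigenvalueWarning(UserWarning):
    """Near-degenerate eigenvalues make eigenvector-dependent output
    solver-dependent."""


class RegeneratedGraphWarning(UserWarning):
    """A generated graph was disconnected and bridge edges were added."""
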