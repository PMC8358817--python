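"""Exception hierarchy and warnings."""


class HemofractalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HemofractalError, ValueError):
    """A configuration object violates its invariants."""


class TreeFormatError(HemofractalError, ValueError):
    """A tree table file (or in-memory record set) violates the dialect."""


class TopologyError(HemofractalError, ValueError):
    """The segment graph is not a single rooted binary tree."""


class DataError(HemofractalError, ValueError):
    """Populated data violate a physical invariant (e.g. flow conservation)."""


class DegenerateInputError(HemofractalError, ValueError):
    """Input is structurally valid but degenerate (zero root flow, zero mean)."""


class InsufficientDataError(HemofractalError, ValueError):
    """Too few generations/points to fit a scaling relation."""


class NumericalError(HemofractalError, RuntimeError):
    """A numerical routine failed to reach its tolerance."""


class ResourceLimitError(HemofractalError, RuntimeError):
    """A safety cap (e.g. maximum segment count) was exceeded."""


class ScaleRangeWarning(UserWarning):
    """The fitted scaling range spans fewer than three decades of cell counts.

    Scale invariance is conventionally accepted when the fit is linear over
    three orders of magnitude of the abscissa; shallower trees cannot provide
    that span, so the fit is reported together with this diagnostic.
    """
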