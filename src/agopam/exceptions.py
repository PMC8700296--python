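"""Exception hierarchy shared across the analysis modules."""


class AgopamError(Exception):
    """Base class for all package-specific errors."""


class UsageError(AgopamError):
    """Inputs are structurally invalid (empty panel, missing group, ...)."""


class DegenerateFitError(AgopamError):
    """A curve fit cannot be performed or did not converge meaningfully."""


class NormalizationError(AgopamError):
    """A reference response is absent or has (near-)zero mean."""


class GeometryError(AgopamError):
    """A geometric operation received degenerate coordinates."""
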