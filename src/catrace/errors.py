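"""Exception hierarchy shared across the package."""


class CatraceError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CatraceError):
    """Input violates a stated contract (timing grid, window bounds, labels)."""


class FormatError(CatraceError):
    """On-disk file does not match the expected schema."""


class DegenerateTraceError(CatraceError):
    """A trace cannot be normalized (non-positive baseline after background subtraction)."""


class InfeasiblePresetError(CatraceError):
    """Generative parameters are mutually inconsistent (mixture mean vs responder fraction)."""


class LayoutError(CatraceError):
    """Image-stack layout cannot place all cells without overlap."""
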