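"""Exception hierarchy for tectotune."""


class TectotuneError(Exception):
    """Base class for all tectotune errors."""


class ConfigurationError(TectotuneError):
    """Invalid protocol, axis, or simulator configuration."""


class AlignmentError(TectotuneError):
    """Trace length does not match the protocol frame count."""


class DegenerateBaselineError(TectotuneError):
    """Baseline fluorescence F0 is non-positive; ΔF/F is undefined."""


class UndefinedWmrError(TectotuneError):
    """All size responses are non-positive; the WMR angle is undefined.

    Callers exclude such neurons explicitly rather than silently zeroing them.
    """


class UndefinedShiftError(TectotuneError):
    """Phase correlation on a constant image has no defined translation."""


class InvalidSegmentError(TectotuneError):
    """A trajectory segment is too short or has non-increasing timestamps."""


class GenerationError(TectotuneError):
    """Synthetic rendering failed (e.g. overlapping ROIs)."""


class DesignError(TectotuneError):
    """Statistical design is degenerate (e.g. single-level factor)."""
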