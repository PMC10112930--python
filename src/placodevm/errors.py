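"""Exception hierarchy for placodevm."""


class PlacodeError(Exception):
    """Base class for all placodevm-specific errors."""


class DegenerateGeometryError(PlacodeError):
    """An edge or cable segment has collapsed to (near-)zero length."""


class DivergenceError(PlacodeError):
    """Time integration produced non-finite positions."""


class NonConvergenceError(PlacodeError):
    """Relaxation or ground-state calibration failed to converge."""


class MissingTagsError(PlacodeError):
    """An operation requires region/cable tags that are not present."""


class InsufficientSpanError(PlacodeError):
    """A vertex track is shorter than the requested measurement window."""


class InsufficientDataError(PlacodeError):
    """Too few usable tracks on one side of the cable."""


class UndefinedNormalizationError(PlacodeError):
    """The baseline radial movement is too close to zero to normalise by."""
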