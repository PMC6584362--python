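"""Exception hierarchy shared across the package."""


class OvimorphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OvimorphError, ValueError):
    """An invalid specification, schedule, script or option value."""


class GeometryError(OvimorphError, ValueError):
    """Degenerate or inconsistent geometry (collinear ring, overlap, ...)."""


class DegenerateDataError(OvimorphError, ValueError):
    """Data without enough variation to fit (zero variance, n too small)."""


class TrackingError(OvimorphError, ValueError):
    """Inconsistent cell-track identities across frames."""


class FormatError(OvimorphError, ValueError):
    """A file that does not match the expected on-disk schema."""
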