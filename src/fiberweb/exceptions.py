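"""Exception hierarchy shared across the package."""


class FiberwebError(ValueError):
    """Base class for all domain errors raised by fiberweb."""


class DegenerateGeometryError(FiberwebError):
    """Geometry cannot host at least one fiber (e.g. porosity too close to 1)."""


class InconsistentMeasurementError(FiberwebError):
    """Measured quantities violate a physical bound (e.g. M2 > M1)."""


class NonInvertibleError(FiberwebError):
    """The forward map is the zero map (k = 0) and cannot be inverted."""


class OverDenseNetworkError(FiberwebError):
    """Realized fiber volume exceeds the RVE volume (porosity < 0)."""


class ResolutionError(FiberwebError):
    """Requested raster scale cannot resolve the thinnest fiber (< 3 px)."""


class NoSignalError(FiberwebError):
    """Image contains no usable foreground signal."""


class CurveValidationError(FiberwebError):
    """A stress-strain record violates its invariants (e.g. non-monotone strain)."""
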