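"""Exception and warning types shared across the toolkit."""


class LamellaKitError(Exception):
    """Base class for all toolkit errors."""


class SingularTransform(LamellaKitError):
    """Affine transform has a non-invertible linear part."""


class DegenerateGeometry(LamellaKitError):
    """Point configuration too degenerate for the requested fit."""


class InvalidAngle(LamellaKitError):
    """Angle outside its physically meaningful range."""


class InvalidOptics(LamellaKitError):
    """Optical parameters violate NA < refractive index or positivity."""


class ImageTooSmall(LamellaKitError):
    """Image smaller than the operation's minimum footprint."""


class FitFailed(LamellaKitError):
    """Model fit did not converge or signal indistinguishable from background."""


class NotEnoughFiducials(LamellaKitError):
    """Fewer point pairs than the transform model requires."""


class EmptyInput(LamellaKitError):
    """Operation received an empty collection."""


class ParseError(LamellaKitError):
    """Malformed protocol or pattern sequence text.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InvalidTarget(LamellaKitError):
    """Lamella target geometry is inconsistent (e.g. inverted extremes)."""


class InvalidGeometry(LamellaKitError):
    """Requested pattern layout is geometrically impossible."""


class ParamError(LamellaKitError):
    """Invalid synthetic-generator parameters."""


class ZeroConfidence(LamellaKitError):
    """Registration attempted on zero-signal images."""


class EmptyMaskWarning(UserWarning):
    """Lamella slab does not intersect the volume; mask is all zero."""


class EmptyMatchingWarning(UserWarning):
    """No mutual-nearest-neighbour pairs within the distance cutoff."""


class ZeroConfidenceWarning(UserWarning):
    """Featureless image(s); registration offset reported as zero."""


class TruncatedStackWarning(UserWarning):
    """Milling front left the specimen before the plan completed."""
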