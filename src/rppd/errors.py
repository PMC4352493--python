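"""Exception types shared across the package."""


class RppdError(Exception):
    """Base class for all package-specific errors."""


class DegenerateImageError(RppdError, ValueError):
    """Raised when an operation needs intensity contrast but the image is constant."""


class EmptyTissueIndexError(RppdError, ValueError):
    """Raised when a random tissue pixel is requested from an exhausted index."""


class PlacementError(RppdError, RuntimeError):
    """Raised when synthetic regions cannot be placed disjointly on the canvas."""
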