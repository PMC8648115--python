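"""Exception hierarchy shared across the package."""


class PromoterscopeError(Exception):
    """Base class for all package errors."""


class InputError(PromoterscopeError, ValueError):
    """Malformed input record or file."""


class ParameterError(PromoterscopeError, ValueError):
    """Invalid parameter value."""


class ValidationError(PromoterscopeError, ValueError):
    """Domain invariant violated (e.g. overlapping gene models)."""


class UnitError(PromoterscopeError, ValueError):
    """Track supplied in the wrong normalization state."""


class BoundaryError(PromoterscopeError, ValueError):
    """Requested window extends beyond the contig or supplied sequence."""


class EmptyLibraryError(PromoterscopeError, ValueError):
    """Normalization requested on a track with zero total signal."""
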