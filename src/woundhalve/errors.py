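"""Exception hierarchy.

All package-specific failures derive from :class:`WoundHalveError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class WoundHalveError(Exception):
    """Base class for all wound-halving errors."""


class InvalidOutlineError(WoundHalveError):
    """Wound outline is degenerate (too few vertices, zero area, out of bounds,
    self-intersecting, or encloses no pixel center)."""


class EmptyMaskError(WoundHalveError):
    """Binary mask contains no foreground pixel."""


class DegenerateMaskError(WoundHalveError):
    """Mask has no 2-D extent (single pixel or collinear pixels): no oriented
    bounding box with positive width exists."""


class CannotHalveError(WoundHalveError):
    """Wound has fewer than 2 pixels; no meaningful halving exists."""


class ViaSchemaError(WoundHalveError):
    """VIA project document is malformed or violates the expected schema."""


class MissingReferenceError(WoundHalveError):
    """An annotation refers to an image or governing outline that is absent."""


class IncompleteDesignError(WoundHalveError):
    """The rating design (images x assessors x rounds) has missing cells."""


class UndefinedICCError(WoundHalveError):
    """ICC is undefined (zero total variance in the rating matrix)."""
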