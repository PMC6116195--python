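"""Exception types shared across the package.

All inherit from :class:`ValueError` so callers that do not care about the
fine-grained category can catch a single built-in type.
"""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable information
    (constant volume, zero-range normalization, empty matrix)."""


class DegenerateOffsetError(ValueError):
    """Co-occurrence displacement leaves no valid voxel pairs inside the ROI."""


class OutOfBoundsError(ValueError):
    """Requested ROI window does not lie fully inside the volume."""
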