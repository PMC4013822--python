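"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A parameter violates its documented constraints."""


class DimensionError(ValueError):
    """An array is too small for the requested operation or shapes mismatch."""


class UnitError(ValueError):
    """A quantity carries the wrong physical unit for the operation."""


class NoObjectError(RuntimeError):
    """No object above threshold anywhere in the volume."""


class EmptyMaskError(RuntimeError):
    """A region-of-interest mask came out empty."""
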