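"""Exception hierarchy shared across the pipeline stages."""


class VtamapError(Exception):
    """Base class for all package errors."""


class DimensionError(VtamapError):
    """Volumes or masks that are expected to share a grid do not."""


class DegenerateInputError(VtamapError):
    """Input is structurally valid but carries no usable information
    (empty mask, constant table, zero spread)."""


class DegeneracyError(VtamapError):
    """A mixture fit was requested with more components than the data
    can support (k exceeds the number of distinct values)."""


class GeometryError(VtamapError):
    """Phantom geometry violates its containment contract."""


class ParameterError(VtamapError):
    """A model parameter is outside its admissible range."""


class ValidationError(VtamapError):
    """A configuration or table is missing required pieces; the message
    enumerates them."""


class StageError(VtamapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
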