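"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """A file or in-memory object does not have the expected layout (missing
    band, missing attribute, malformed metadata)."""


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


class SizingError(ValueError):
    """A requested synthetic layout does not fit the grid."""


class DanglingReferenceError(KeyError):
    """A report or event references a compartment id that does not exist."""


class SamplingError(ValueError):
    """Not enough valid pixels to draw the requested sample."""


class DegenerateInputError(ValueError):
    """A statistical routine received constant or otherwise degenerate data."""


class TrainingError(ValueError):
    """The training set cannot support fitting (e.g. a single class)."""
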