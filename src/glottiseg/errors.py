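"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`GlottisegError`, so callers (and
the CLI) can distinguish pipeline failures from programming errors.
"""


class GlottisegError(Exception):
    """Base class for all pipeline errors."""


class FormatError(GlottisegError):
    """Input data has the wrong shape, channel count, or file format."""


class ParameterError(GlottisegError, ValueError):
    """A parameter is out of its documented range."""


class InsufficientFramesError(GlottisegError):
    """The video has too few frames for the requested operation."""


class NoMotionError(GlottisegError):
    """The total-variation map is identically zero: nothing moves."""


class DegenerateSequenceError(GlottisegError):
    """A mask sequence is empty in every frame; no glottal signal exists."""


class DegenerateCandidateError(GlottisegError):
    """A segmentation candidate produced no usable spectrum."""


class OptimizationFailedError(GlottisegError):
    """Every candidate on the parameter grid was degenerate."""


class InsufficientCyclesError(GlottisegError):
    """Fewer than two glottal cycles were detected."""
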