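"""Exception hierarchy shared across the pipeline stages."""


class PhagekitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PhagekitError, ValueError):
    """A precondition on user-supplied values was violated."""


class InvalidGeometryError(InvalidInputError):
    """Capsid geometry is physically impossible (e.g. shell thicker than radius)."""


class CalibrationError(PhagekitError):
    """Root finding for a model parameter failed within the given bounds."""


class UndefinedDistanceError(PhagekitError):
    """A pairwise distance cannot be computed (no comparable sites, or saturation)."""


class LabelError(InvalidInputError):
    """Labels of two structures (distances, links) do not match up."""


class ClassificationError(InvalidInputError):
    """A codon cannot be placed in the degeneracy scheme (stop or ambiguous)."""


class UntestableError(PhagekitError):
    """A selection test cannot be carried out (all pairs saturated)."""


class DegenerateVarianceError(PhagekitError):
    """The bootstrap variance is zero, so no z statistic exists."""


class ParseError(PhagekitError):
    """A file could not be parsed; message carries location information."""
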