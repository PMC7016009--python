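"""Exception hierarchy.

All shapecat errors derive from :class:`ShapecatError` so callers can catch
the package's failures with a single ``except`` clause; each subclass marks a
distinct contract violation (alignment, degeneracy, parsing, ...).
"""


class ShapecatError(Exception):
    """Base class for all shapecat errors."""


class ValidationError(ShapecatError, ValueError):
    """Input object violates a structural invariant (shape, symmetry, labels)."""


class AlignmentError(ValidationError):
    """Two objects that must share condition ids/order do not."""


class UndefinedCorrelationError(ShapecatError, ValueError):
    """A correlation is requested on a zero-variance (constant) vector."""


class DegenerateModelError(ShapecatError, ValueError):
    """A design factor has too few levels to build a model RDM."""


class DegeneratePartialError(ShapecatError, ValueError):
    """A control RDM is (near-)collinear with a compared RDM."""


class DesignError(ShapecatError, ValueError):
    """A stimulus design does not support the requested procedure."""


class InsufficientDataError(ShapecatError, ValueError):
    """Too few observations/levels for the requested statistic."""


class ParseError(ShapecatError, ValueError):
    """A delimited input file is malformed; message names the location."""
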