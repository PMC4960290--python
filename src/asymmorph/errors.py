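"""Exception hierarchy for the toolkit."""


class AsymmorphError(Exception):
    """Base class for all toolkit errors."""


class ParseError(AsymmorphError):
    """A file could not be parsed; the message names the offending line."""


class StructuralError(AsymmorphError):
    """Inconsistent structure across specimens (landmark count, labels, dims)."""


class DegeneracyError(AsymmorphError):
    """Geometrically degenerate input (collinear/coincident landmarks, zero size)."""


class ConvergenceError(AsymmorphError):
    """An iterative fit failed to converge within its iteration budget."""


class DimensionError(AsymmorphError):
    """Mismatched vector/matrix dimensions."""
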