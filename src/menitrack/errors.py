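"""Exception hierarchy for menitrack."""


class MenitrackError(Exception):
    """Base class for all menitrack errors."""


class InvalidSchemeError(MenitrackError):
    """Gradient scheme violates its invariants (e.g. zero directions with b > 0)."""


class InsufficientSchemeError(MenitrackError):
    """Scheme cannot support a tensor fit (< 6 non-collinear directions or no b0)."""


class GradientTableFormatError(MenitrackError):
    """bval/bvec pair is malformed (row/column mismatch)."""


class PhantomSpecError(MenitrackError):
    """Phantom geometry parameters are inconsistent or do not fit the grid."""


class DegenerateGeometryError(MenitrackError):
    """Mask geometry is degenerate (empty, single point, collinear cloud)."""


class ParameterError(MenitrackError):
    """Invalid parameter value for an operation."""


class StreamlineFormatError(MenitrackError):
    """Streamline container file is malformed."""
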