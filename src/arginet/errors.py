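"""Exception hierarchy for the pipeline.

All errors derive from :class:`ArginetError` so callers can catch the
package's failures with a single ``except`` clause; each stage raises the
most specific subclass that applies.
"""


class ArginetError(ValueError):
    """Base class for all pipeline errors."""


class InvalidDesignError(ArginetError):
    """Sample design violates its invariants (duplicate labels, <2 replicates...)."""


class EmptyInputError(ArginetError):
    """An input collection that must be non-empty is empty."""


class InvalidRateError(ArginetError):
    """A proportion parameter lies outside its admissible range."""


class InvalidIntervalError(ArginetError):
    """An interval parameter is empty or outside its admissible range."""


class InvalidThresholdError(ArginetError):
    """A count threshold exceeds what the data can support."""


class DegenerateSampleError(ArginetError):
    """A sample has no usable values (zero library size, all-missing column)."""


class UnknownConditionError(ArginetError):
    """A contrast references a condition absent from the design."""


class MissingContrastError(ArginetError):
    """A required contrast result was not supplied."""


class EmptyPathwayError(ArginetError):
    """A pathway has no genes present in the expression matrix."""


class InvalidPermutationsError(ArginetError):
    """Number of permutations/draws must be >= 1."""


class TooLargeError(ArginetError):
    """Exhaustive enumeration bound exceeded."""


class InvalidPValueError(ArginetError):
    """A p-value lies outside [0, 1]."""


class InvalidS0Error(ArginetError):
    """The s0 fudge factor must be non-negative."""


class UndefinedCVError(ArginetError):
    """Coefficient of variation undefined (zero mean)."""


class UndefinedFractionError(ArginetError):
    """Isotopologue fraction undefined (zero total pool)."""


class UndefinedRatioError(ArginetError):
    """Label ratio undefined (zero unlabelled pool)."""


class UndefinedNormalizationError(ArginetError):
    """Tracer normalization undefined (zero tracer intensity)."""


class InvalidSizeError(ArginetError):
    """A requested size exceeds the available universe."""


class InvalidBetaError(ArginetError):
    """Prize scaling beta must be positive."""
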