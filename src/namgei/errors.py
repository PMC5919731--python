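"""Exception types shared across the package."""


class NamgeiError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(NamgeiError, ValueError):
    """A simulation or trial design violates its invariants."""


class MissingCheckError(NamgeiError, ValueError):
    """A block contains no check plots, so no field adjustment is possible."""


class InsufficientSegregationError(NamgeiError, ValueError):
    """A marker segregates in too few families for the requested analysis."""


class DegenerateInputError(NamgeiError, ValueError):
    """Input is structurally valid but carries no usable information."""


class ValidationError(NamgeiError, ValueError):
    """Cross-file consistency check failed (e.g. phenotype IDs absent from genotypes)."""
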