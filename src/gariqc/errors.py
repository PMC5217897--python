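"""Exception hierarchy shared by all gariqc modules."""


class GariQCError(Exception):
    """Base class for all gariqc errors."""


class DegenerateInputError(GariQCError, ValueError):
    """Input is structurally valid but carries no usable signal
    (zero total mass, empty replicate list, zero volume, ...)."""


class SchemaError(GariQCError, ValueError):
    """Tabular input does not match the expected schema
    (missing columns, misaligned class counts, non-numeric cells)."""


class InconsistentReadingError(GariQCError, ValueError):
    """A reading violates a physical consistency constraint
    (e.g. dry weight exceeding fresh weight)."""


class FailedCombustionError(GariQCError, ValueError):
    """A calorimeter trace shows no positive temperature rise."""


class InsufficientTraceError(GariQCError, ValueError):
    """A temperature trace has too few points in a drift-fit window."""


class UnbalancedDesignError(GariQCError, ValueError):
    """A factorial dataset is not a balanced 2x2 design."""


class InconsistentTruthError(GariQCError, ValueError):
    """Declared simulation ground truth implies a physically
    impossible observation (e.g. non-positive temperature rise)."""
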