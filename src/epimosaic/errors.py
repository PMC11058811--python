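"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class EmptyTraceError(ValidationError):
    """A basal-layer path sampled only background pixels."""


class DegenerateTraceError(ValidationError):
    """Single-label trace: the composition-conditional null has one
    arrangement, so the permutation test is not testable (report as such,
    not as p = 1)."""


class CompositionMismatchError(ValidationError):
    """A run carries a label whose composition probability is zero; the
    composition cannot have come from the same trace."""


class UndefinedFractionError(ValidationError):
    """Area fraction requested on a mask with no non-background pixels."""


class FitConvergenceError(RuntimeError):
    """The coverage-curve optimizer failed; message carries the optimizer
    status and a summary of the data."""
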