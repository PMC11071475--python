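"""Exception and warning types shared across the pipeline."""


class ParameterError(ValueError):
    """An input parameter violates its documented constraints."""


class StructuralError(ValueError):
    """Arrays or records have incompatible shapes or missing fields."""


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge after multi-start attempts."""


class DegenerateThresholdError(ValueError):
    """Thresholding is undefined, e.g. zero spread in a constant image."""


class DegenerateFitWarning(UserWarning):
    """The fitted model collapsed (e.g. both exponential phases coincide)."""
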