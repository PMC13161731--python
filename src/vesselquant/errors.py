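"""Exception types shared across the package."""


class InputError(ValueError):
    """Raised when an input violates a documented precondition."""


class UndefinedMetricError(ArithmeticError):
    """Raised when a ratio metric is undefined (0/0), which is distinct from 0.

    Low-prevalence regions make this distinction material: a region with no
    predictions has undefined precision, not perfect or zero precision.
    """
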