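"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An input violates a precondition (wrong shape, non-positive duration, ...)."""


class UndefinedStatisticError(ValueError):
    """The requested statistic is mathematically undefined for this input
    (e.g. a coefficient of variation at mean zero, a correlation of a
    constant vector)."""


class SchemaError(ValueError):
    """A file does not match the expected column schema or units."""
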