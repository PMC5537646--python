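"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input value lies outside the domain an operation is defined on."""


class SchemaError(ValueError):
    """A cohort file violates the documented CSV schema."""


class ConvergenceError(RuntimeError):
    """A model fit failed to converge (separation, boundary pathologies, ...)."""
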