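"""Exception types shared across the package."""


class ContractError(ValueError):
    """An argument violates a documented precondition."""


class AtlasSizeError(ContractError):
    """Requested atlas grid is too small to resolve every segment band."""


class CohortValidationError(ContractError):
    """A cohort record violates the interchange schema.

    The message names the offending patient id and field where known.
    """


class EmptyResultError(ValueError):
    """A query matched no patients."""
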