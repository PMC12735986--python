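"""Package exception types."""


class ParameterValidationError(ValueError):
    """A model parameter violates its physical constraint.

    Carries the offending field name so callers (and the CLI) can point
    at exactly which input was rejected.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class GapDomainError(ValueError):
    """An energy lies outside the gap where evanescent modes are defined.

    Outside [εH, εL] the transfer-matrix eigenvalues are unimodular
    (|trace| ≤ 2 never holds in-gap; propagating Bloch modes appear
    instead) and a decay rate β is not defined.
    """
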