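"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A required column or declared level is missing or unknown."""


class CohortValidationError(ValueError):
    """One or more rows violate the cohort invariants.

    Attributes
    ----------
    failures : list of (row_index, column, message)
        Every violating row is reported, not just the first.
    """

    def __init__(self, failures):
        self.failures = list(failures)
        lines = [f"row {r}: column '{c}': {m}" for r, c, m in self.failures]
        super().__init__(
            f"{len(self.failures)} validation failure(s):\n" + "\n".join(lines)
        )


class EstimationError(RuntimeError):
    """A model fit failed (separation, rank deficiency, empty group/class)."""
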