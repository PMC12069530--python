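"""Exception hierarchy shared across the package."""


class OiprError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OiprError):
    """A file or table does not have the documented layout (missing columns,
    wrong dtypes, unknown categories)."""


class ValidationError(OiprError):
    """Structurally valid input that violates a domain invariant.

    Carries a row-addressed report in ``problems`` (list of strings).
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        super().__init__(message)
        self.problems = problems or []

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.problems:
            return base + "\n" + "\n".join("  - " + p for p in self.problems)
        return base


class ParameterError(OiprError):
    """An argument outside its documented domain."""


class EligibilityError(OiprError):
    """No neuron (or not enough trials) satisfies a selection threshold."""
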