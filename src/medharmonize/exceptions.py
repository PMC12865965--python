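"""Exception hierarchy for the harmonization pipeline."""


class MedHarmonizeError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(MedHarmonizeError):
    """A delimited input file is missing a required header column."""


class ReferentialIntegrityError(MedHarmonizeError):
    """A foreign key in a reference table does not resolve."""

    def __init__(self, message: str, offending_keys: list[str] | None = None):
        super().__init__(message)
        self.offending_keys = offending_keys or []


class ClassNumberParseError(MedHarmonizeError):
    """A therapeutic classification number does not match the expected grammar."""


class DictionaryConflictError(MedHarmonizeError):
    """The same variant key maps to two different canonical names."""


class ConfigurationError(MedHarmonizeError):
    """An invalid or inconsistent pipeline configuration."""


class ValidationError(MedHarmonizeError):
    """Input records violate a precondition (bad ids, missing keys...)."""
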