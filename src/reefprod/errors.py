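"""Exception hierarchy shared across the pipeline."""


class ReefprodError(Exception):
    """Base class for all package errors."""


class SchemaError(ReefprodError):
    """An input table is missing required columns or has malformed values."""


class ValidationError(ReefprodError):
    """A row or table violates a documented invariant."""


class IntegrityError(ReefprodError):
    """Referential integrity between tables is broken."""


class ClassificationError(ReefprodError):
    """A diel-habit label is outside the closed diurnal/nocturnal/both set."""


class StrictJoinError(ReefprodError):
    """Species unmatched in traits or diel tables under strict joining."""


class FitError(ReefprodError):
    """The hierarchical model cannot be fitted on the given data."""
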