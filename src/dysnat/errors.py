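"""Exception types shared across the pipeline."""


class DysnatError(Exception):
    """Base class for all package errors."""


class ConfigError(DysnatError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class InputError(DysnatError, ValueError):
    """Invalid input data (schema, referential integrity, value domain)."""


class ValidationError(DysnatError, ValueError):
    """A single value failed a domain check (e.g. a malformed ICD-10 code)."""


class FitError(DysnatError, RuntimeError):
    """A model fit failed (non-convergence, separation, rank deficiency)."""


class ComparabilityError(DysnatError, ValueError):
    """Model fits being compared were not estimated on the same rows."""
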