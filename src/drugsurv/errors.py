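"""Exception hierarchy shared across the package."""


class DrugsurvError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DrugsurvError):
    """An input file violates its expected tabular/GMT format."""


class ConfigError(DrugsurvError):
    """A configuration value is invalid or inconsistent."""


class UsageError(DrugsurvError):
    """An operation was called outside its preconditions."""
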