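"""Exception hierarchy shared across the pipeline stages."""


class MirsigError(Exception):
    """Base class for all errors raised by mirsig."""


class ConfigurationError(MirsigError, ValueError):
    """A simulation or pipeline configuration violates one of its invariants."""


class FormatError(MirsigError, ValueError):
    """An input file does not conform to the expected delimited-text layout."""


class ValidationError(MirsigError, ValueError):
    """Inputs to an operation violate its preconditions."""


class StageOrderError(ValidationError):
    """A stage was invoked before a prerequisite stage (e.g. normalization
    before ceiling imputation of undetected wells)."""
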