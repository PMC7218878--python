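"""Exception hierarchy shared across the pipeline.

Validation errors signal bad configuration or parameters (CLI exit code 2);
data errors signal malformed or inconsistent input files (exit code 3).
"""


class PTTBPError(Exception):
    """Base class for all package errors."""


class ValidationError(PTTBPError):
    """Invalid configuration, parameters, or preconditions."""


class DataError(PTTBPError):
    """Malformed, inconsistent, or insufficient input data."""
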