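"""Package exception types, mapped onto CLI exit codes."""


class HospvarError(Exception):
    """Base class for package errors."""


class ValidationError(HospvarError):
    """Invalid input data or configuration (CLI exit code 1)."""


class ConvergenceError(HospvarError):
    """MCMC diagnostics failed and summaries were requested (CLI exit code 2)."""
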