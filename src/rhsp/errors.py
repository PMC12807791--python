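"""Exception hierarchy with CLI exit codes.

Exit-code contract: 0 success, 2 input error, 3 configuration error,
4 numeric failure.
"""


class RHSPError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(RHSPError):
    """Unreadable, malformed or degenerate input data."""

    exit_code = 2


class ConfigurationError(RHSPError):
    """Invalid or inconsistent analysis configuration."""

    exit_code = 3


class NumericError(RHSPError):
    """A numeric step failed (non-positive volume, divergence, ...)."""

    exit_code = 4
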