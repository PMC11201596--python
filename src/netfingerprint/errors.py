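"""Exception hierarchy.

Three error families map onto distinct CLI exit codes so shell callers can
tell a bad invocation from a bad input file from a failed simulation:
parameter/config errors exit 2, data errors 3, simulation errors 4.
"""


class NetfingerprintError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(NetfingerprintError, ValueError):
    """An argument or configuration value is invalid."""

    exit_code = 2


class ConfigError(ParameterError):
    """A run configuration file is missing, malformed, or inconsistent."""

    exit_code = 2


class DataError(NetfingerprintError, ValueError):
    """Input data violates a contract (missing values, wrong shape, ...)."""

    exit_code = 3


class SimulationError(NetfingerprintError, RuntimeError):
    """A synthetic cohort could not be generated as requested."""

    exit_code = 4
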