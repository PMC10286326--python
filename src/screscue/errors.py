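"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so that scripted callers can
tell bad configuration, malformed files and computation failures apart.
"""


class ScRescueError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ScRescueError):
    """Invalid parameter values or an inconsistent pipeline configuration."""

    exit_code = 2


class InputError(ScRescueError):
    """Well-formed but semantically invalid input (mismatched ids, empty groups...)."""

    exit_code = 2


class FormatError(ScRescueError):
    """A file that cannot be parsed as the expected format."""

    exit_code = 3


class ComputationError(ScRescueError):
    """A stage failed during numerical work."""

    exit_code = 4
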