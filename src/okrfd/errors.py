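"""Exception hierarchy with distinct exit codes for the CLI."""


class OkrfdError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(OkrfdError):
    """Bad or unreadable input file (missing index, unknown contig, ...)."""

    exit_code = 2


class ParameterError(OkrfdError):
    """Invalid parameter value (even span, non-stochastic matrix, ...)."""

    exit_code = 3


class DegenerateInputError(OkrfdError):
    """Input lacks the structure the operation needs (e.g. constant deltas)."""

    exit_code = 4


class UndefinedResultError(OkrfdError):
    """The requested quantity is undefined on this input."""

    exit_code = 5
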