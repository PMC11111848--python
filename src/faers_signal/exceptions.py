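"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command line interface:
configuration error -> 2, input error -> 3, statistical precondition -> 4.
"""


class FaersSignalError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(FaersSignalError):
    """Invalid run configuration (bad thresholds, malformed mapping, ...)."""

    exit_code = 2


class InputError(FaersSignalError):
    """Missing or unreadable input data."""

    exit_code = 3


class SmallSampleError(FaersSignalError):
    """A statistical routine was called with too few observations."""

    exit_code = 4


class DegenerateDataError(FaersSignalError):
    """Data admit no finite maximum-likelihood fit (e.g. constant sample)."""

    exit_code = 4
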