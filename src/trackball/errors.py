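"""Exception hierarchy.

``InputDataError`` covers malformed files, invalid configuration and contract
violations on user-supplied data; ``ComputationError`` covers failures inside
the processing/estimation stages. The CLI maps them to distinct exit codes.
"""


class TrackballError(Exception):
    """Base class for all package errors."""


class InputDataError(TrackballError, ValueError):
    """Invalid input data, file or configuration."""


class ComputationError(TrackballError, RuntimeError):
    """A processing or estimation stage failed."""
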