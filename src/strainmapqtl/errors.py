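"""Exception hierarchy.

Three failure classes are distinguished so that callers (and the CLI exit
codes) can tell bad arguments from bad data from bad pipeline state.
"""


class StrainMapError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(StrainMapError, ValueError):
    """A function was called with arguments violating its preconditions."""


class InvalidInputError(StrainMapError, ValueError):
    """Input data violates a structural invariant (bad file, bad matrix)."""


class InvalidStateError(StrainMapError, RuntimeError):
    """A pipeline stage reached an unusable state (e.g. empty result set)."""
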