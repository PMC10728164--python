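"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``DataInconsistencyError``
to exit code 3; everything else is a plain bug.
"""


class NtdmsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NtdmsError):
    """Invalid configuration, missing fixture, or bad parameter value."""


class DataInconsistencyError(NtdmsError):
    """Input data that contradicts itself (e.g. conflicting fragment evidence)."""


class UnknownResidueError(ConfigurationError):
    """A sequence contains a letter outside the 20 canonical amino acids."""

    def __init__(self, code: str, position: int):
        self.code = code
        self.position = position
        super().__init__(f"unknown residue code {code!r} at position {position}")
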