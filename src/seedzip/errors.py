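"""Exception taxonomy shared across the package.

Data-level problems (bad symbols, broken containers, failed integrity
checks) derive from :class:`SeedzipError` so the CLI can map them to a
single exit code; programming-contract violations derive from
:class:`ContractViolation` and indicate misuse of the library API.
"""


class SeedzipError(Exception):
    """Base class for all data-level errors raised by seedzip."""


class ValidationError(SeedzipError):
    """Input sequence violates the alphabet or record contract."""


class ContractViolation(SeedzipError):
    """A library API was called in a way that breaks its preconditions."""


class ContainerError(SeedzipError):
    """Base class for errors raised while parsing a compressed container."""


class NotAContainerError(ContainerError):
    """The byte stream does not start with the container magic."""


class UnsupportedVersionError(ContainerError):
    """The container declares a format version this build cannot read."""


class MalformedContainerError(ContainerError):
    """The container is truncated or internally inconsistent."""


class IntegrityError(SeedzipError):
    """Decompression produced output that fails the recorded checks."""
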