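"""Exception hierarchy.

Everything raised deliberately by qeegkit derives from :class:`QeegError`,
so callers (and the CLI) can separate expected input problems from bugs.
"""


class QeegError(Exception):
    """Base class for all qeegkit errors."""


class ValidationError(QeegError, ValueError):
    """A domain object violates one of its invariants."""


class InputError(QeegError, ValueError):
    """An operation was called with unusable inputs (wrong length, range...)."""


class ConfigurationError(QeegError, ValueError):
    """A configuration value is missing or out of its admissible range."""


class FormatError(QeegError):
    """A file could not be parsed in the expected on-disk format."""


class UnitError(FormatError):
    """A file lacks, or has an unusable, physical-unit declaration."""
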