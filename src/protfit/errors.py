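"""Exception hierarchy.

Errors are categorized so the CLI can map them to exit diagnostics:
configuration problems, malformed files, inconsistent data, and
violations of domain invariants.
"""


class ProtfitError(Exception):
    """Base class for all package errors."""


class ConfigError(ProtfitError):
    """Invalid configuration: bad option values, incompatible strategies."""


class FormatError(ProtfitError):
    """A file does not conform to its declared format."""


class DataError(ProtfitError):
    """Well-formed input that is internally inconsistent or unusable."""


class ValidationError(DataError):
    """A domain invariant is violated (e.g. wild-type residue mismatch)."""
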