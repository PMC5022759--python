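"""Exception hierarchy shared across the package.

Exit-code contract for the command line front end: data problems
(unreadable files, shape mismatches) map to exit code 1, configuration
problems (bad parameters, out-of-bounds seeds, empty candidate masks)
to exit code 2.
"""


class GasegError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class DataError(GasegError):
    """Input data is malformed or inconsistent (shape mismatch, NaNs...)."""

    exit_code = 1


class FormatError(DataError):
    """A file could not be read or written in a supported format."""


class ConfigurationError(GasegError):
    """Invalid parameter values or an unusable run configuration."""

    exit_code = 2


class SeedError(ConfigurationError):
    """Seed coordinates are out of bounds, duplicated, or ineligible."""
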