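"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`ReverseEcologyError` so the
command-line layer can distinguish bad input (exit code 1) from internal
faults (exit code 2).
"""


class ReverseEcologyError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ReverseEcologyError):
    """A flat file or table could not be parsed; names the entry and line."""


class FormatError(ReverseEcologyError):
    """A table is structurally invalid (e.g. a required column is missing)."""


class LookupError_(ReverseEcologyError):
    """An organism code or identifier could not be resolved."""


class ConnectivityError(ReverseEcologyError):
    """No network access and no local cache to fall back on."""


class ReconstructionError(ReverseEcologyError):
    """Network reconstruction was attempted on inadmissible input."""


class EmptySeedSetError(ReverseEcologyError):
    """An interaction index was requested for a species with no seed set."""
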