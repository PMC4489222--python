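"""Error taxonomy shared by all modules.

Every exception carries a stable ``code`` string so the CLI can print a
machine-greppable identifier and map the failure onto an exit-code class:
usage (bad flags), validation (bad query against good data), or data/config
(broken registry, unreadable files, inconsistent alignments).
"""

from __future__ import annotations


class MsamapError(Exception):
    """Base class; ``code`` identifies the error class in CLI output."""

    code = "ERROR"

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"{self.code}: {self.message}"


# --- usage -----------------------------------------------------------------

class UsageError(MsamapError):
    code = "USAGE_ERROR"


# --- parsing / validation of queries --------------------------------------

class ParseError(MsamapError):
    code = "PARSE_ERROR"


class ValidationError(MsamapError):
    """Base for violations of the query limits and endpoint rules."""


class TooManyRangesError(ValidationError):
    code = "TOO_MANY_RANGES"


class RangeTooLongError(ValidationError):
    code = "RANGE_TOO_LONG"


class EndpointsOutOfOrderError(ValidationError):
    code = "ENDPOINTS_OUT_OF_ORDER"


class UnknownResidueError(ValidationError):
    code = "UNKNOWN_RESIDUE"


class NoDataError(ValidationError):
    """Raised when a query endpoint has no equivalent position in the
    lookup sequence (engineered inserts, unalignable residues)."""

    code = "NO_DATA"

    def __init__(self, message: str = "No data available in table"):
        super().__init__(message)


# --- data / config ---------------------------------------------------------

class DataError(MsamapError):
    """Base for problems in the input data files themselves."""


class FormatError(DataError):
    code = "FORMAT_ERROR"


class DuplicateIdError(DataError):
    code = "DUPLICATE_ID"


class DuplicateResidueKeyError(DataError):
    code = "DUPLICATE_RESIDUE_KEY"


class EmptyInputError(DataError):
    code = "EMPTY_INPUT"


class InvalidAlignmentError(DataError):
    code = "INVALID_ALIGNMENT"


class LookupNotFoundError(DataError):
    code = "LOOKUP_NOT_FOUND"


class LookupMismatchError(DataError):
    code = "LOOKUP_MISMATCH"


class ConfigError(DataError):
    code = "CONFIG_ERROR"


class UnknownStructureError(DataError):
    code = "UNKNOWN_STRUCTURE"


class AmbiguousAlignmentError(DataError):
    code = "AMBIGUOUS_ALIGNMENT"
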