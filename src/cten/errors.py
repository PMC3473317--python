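"""Exception taxonomy shared across the package.

Exit-code mapping used by the CLI: ParameterError -> 2, FormatError /
ValidationError -> 3, NoGenesFoundError / EmptyDatabaseError -> 4.
"""


class CtenError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CtenError, ValueError):
    """An argument is outside its documented domain (e.g. threshold t <= 1)."""


class FormatError(CtenError):
    """A file or text input does not conform to the expected dialect."""


class ParseError(FormatError):
    """A gene-list text could not be parsed under the declared identifier type."""


class ValidationError(CtenError):
    """Parsed data violates a structural invariant (negative value, missing sample...)."""


class NoGenesFoundError(CtenError):
    """None of a list's identifiers map into the database universe."""

    def __init__(self, list_name: str):
        super().__init__(f"No genes found in the database (list {list_name!r})")
        self.list_name = list_name


class EmptyDatabaseError(CtenError):
    """Signature construction produced no HECS gene for any cell type."""
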