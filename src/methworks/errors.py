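"""Exception hierarchy.

``UserError`` marks problems attributable to the caller's inputs or
configuration (CLI exit code 1); anything else escaping the library is
treated as an internal error (exit code 2).
"""


class UserError(ValueError):
    """Invalid input data or configuration supplied by the caller."""


class DataError(UserError):
    """Malformed or inconsistent dataset content."""
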