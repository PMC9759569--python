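"""Exception hierarchy.

``InputError`` maps to CLI exit code 2, ``DegenerateDataError`` to exit code 3.
"""


class CommstabError(Exception):
    """Base class for all package errors."""


class InputError(CommstabError):
    """Malformed or inconsistent user input (bad CSV, missing columns, ...)."""


class DegenerateDataError(CommstabError):
    """Data that is structurally valid but makes a quantity undefined
    (e.g. zero total variance, constant donor series)."""
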