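"""Exception hierarchy shared across the package.

``BindmodeError`` is the common base; ``DataError`` marks problems with
user-supplied input files or tables (CLI exit code 2), ``StructureError``
and ``TableError`` refine it for structural and tabular inputs.
"""


class BindmodeError(Exception):
    """Base class for all package-specific errors."""


class DataError(BindmodeError):
    """Invalid or inconsistent input data."""


class StructureError(DataError):
    """Problem with a structure file or pose ensemble."""


class TableError(DataError):
    """Problem with a delimited-text table."""
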