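"""Exception hierarchy shared across the pipeline.

Two broad classes are distinguished so the CLI can map them to distinct
exit codes: problems with the *input* (bad files, invalid records, bad
parameters) versus problems arising *during computation* (undefined
quantities, degenerate designs).
"""


class DroughtScreenError(Exception):
    """Base class for all pipeline errors."""


class InputError(DroughtScreenError):
    """Invalid input data or parameters (CLI exit code 2)."""


class SchemaError(InputError):
    """A delimited file does not match its expected schema."""


class DuplicateKeyError(InputError):
    """A key column contains repeated values."""


class MissingDataError(InputError):
    """A required design cell is absent; the message lists the cell(s)."""


class ComputationError(DroughtScreenError):
    """A quantity is undefined for the given data (CLI exit code 3)."""


class FixtureError(DroughtScreenError):
    """The packaged reference table failed its integrity check."""
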