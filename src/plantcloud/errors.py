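"""Exception hierarchy.

``CloudError`` marks data/format problems (CLI exit code 2); plain
``ValueError``/``TypeError`` are reserved for programming errors in
parameters and are also treated as data errors by the CLI.
"""


class CloudError(Exception):
    """Base class for data and format errors."""


class ParseError(CloudError):
    """A text input could not be parsed; message names the line."""


class FormatError(CloudError):
    """A structured file (PLY/HDF5/CSV) violates the expected layout."""
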