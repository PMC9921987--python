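"""Exception types for anticipated domain errors.

These are the errors the CLI turns into one-line diagnostics (exit code 1)
rather than stack traces: malformed input files, broken partition
invariants, references to unknown sequence ids, and the like.
"""


class CompletPlusError(Exception):
    """Base class for anticipated domain errors."""


class FormatError(CompletPlusError):
    """A file does not conform to its declared format."""


class ClusteringError(CompletPlusError):
    """A clustering violates the partition invariants."""


class UnknownIdError(CompletPlusError):
    """An operation referenced a sequence id that is not present."""
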