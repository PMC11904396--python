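"""Exception hierarchy.

Parse/format problems (malformed files) and validation problems (well-formed
files whose content breaks an invariant) are kept distinct so callers — in
particular the command-line wrapper — can map them to different exit codes.
"""


class GeneCollapseError(Exception):
    """Base class for all package errors."""


class FormatError(GeneCollapseError):
    """The input file does not conform to its declared format."""


class DataValidationError(GeneCollapseError):
    """The input parsed but violates a content invariant."""


class GenerationError(GeneCollapseError):
    """A synthetic dataset request cannot be laid out."""
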