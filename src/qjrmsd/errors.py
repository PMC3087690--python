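"""Exception hierarchy.

All package-level failures derive from :class:`QjError` so callers (and the
CLI) can map error families to distinct exit codes: input/correspondence
problems, file-format problems, and numeric problems.
"""


class QjError(Exception):
    """Base class for all qjrmsd errors."""


class CorrespondenceError(QjError):
    """The two coordinate sets cannot be put in 1:1 atom correspondence."""


class EmptyInputError(QjError):
    """A coordinate set or ensemble with no atoms/members was supplied."""


class EnsembleError(QjError):
    """An ensemble violates its invariants (e.g. heterogeneous atom counts)."""


class FormatError(QjError):
    """A structure or matrix file could not be parsed."""


class NumericError(QjError):
    """Non-finite or otherwise invalid numeric input."""


class GenerationError(QjError):
    """The synthetic chain generator could not satisfy its constraints."""
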