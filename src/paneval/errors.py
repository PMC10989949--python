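"""Exception hierarchy.

Each class carries the process exit code the CLI maps it to:
usage/config errors exit 2, malformed input files exit 3, annotation
conflicts exit 4, anything else 1.
"""


class PanevalError(Exception):
    """Base class for all paneval errors."""

    exit_code = 1


class UsageError(PanevalError):
    """The operation was invoked incorrectly (too few profiles, empty input...)."""

    exit_code = 2


class ConfigError(UsageError):
    """A parameter is outside its legal range."""


class FormatError(PanevalError):
    """An input file does not conform to its declared format."""

    exit_code = 3


class DuplicateGeneError(FormatError):
    """The same gene appears in two clusters, violating profile disjointness."""


class UnknownGenomeError(FormatError):
    """A gene token cannot be resolved to a genome."""


class AnnotationConflictError(PanevalError):
    """A gene is assigned two different COG identifiers."""

    exit_code = 4
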