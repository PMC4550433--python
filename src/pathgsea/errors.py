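"""Exception hierarchy.

The CLI maps these onto exit codes: :class:`DataError` (and subclasses)
exit 1, :class:`ConfigurationError` exit 2.
"""


class PathgseaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PathgseaError):
    """Invalid configuration (dimensions, ranges, missing referenced items)."""


class DataError(PathgseaError):
    """Invalid data values (e.g. non-positive TG, P-values outside (0, 1])."""


class FormatError(DataError):
    """Malformed input file; carries the path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = str(path) if path is not None else ""
        if line is not None:
            loc = f"{loc}:{line}" if loc else f"line {line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class PipelineError(PathgseaError):
    """A pipeline stage could not produce output (e.g. no SNP survives QC)."""
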