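"""Exception types shared across the package."""


class PeakgeneError(Exception):
    """Base class for all package errors."""


class ParseError(PeakgeneError, ValueError):
    """A malformed input file; message names the file and 1-based line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


class ConfigError(PeakgeneError, ValueError):
    """An inconsistent run configuration, detected before any computation."""
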