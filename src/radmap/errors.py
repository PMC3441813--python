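"""Exception types shared across the package."""


class RadmapError(Exception):
    """Base class for all package errors."""


class ConfigError(RadmapError, ValueError):
    """An invalid simulation or analysis configuration."""


class UninformativeMarkerError(RadmapError, ValueError):
    """A marker vector is constant (all present or all absent) over the
    informative clones and carries no linkage information."""


class NoDataError(RadmapError, ValueError):
    """No informative observations are available for an estimate."""


class ParseError(RadmapError, ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}:"
        if line is not None:
            loc += f"{line}: "
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line
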