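"""Exception hierarchy."""


class CGStackError(Exception):
    """Base class for all package errors."""


class ParseError(CGStackError):
    """A structure/trajectory/config file failed to parse.

    Carries the file path and, where known, the 1-based line number and
    frame index at which parsing failed.
    """

    def __init__(self, message, path=None, line=None, frame=None):
        parts = []
        if path is not None:
            parts.append(str(path))
        if frame is not None:
            parts.append(f"frame {frame}")
        if line is not None:
            parts.append(f"line {line}")
        prefix = ", ".join(parts)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = path
        self.line = line
        self.frame = frame


class ConfigError(CGStackError):
    """A mapping-scheme or run configuration is invalid."""


class UnsupportedFeatureError(CGStackError):
    """Input uses a feature outside the supported subset (e.g. triclinic box)."""


class MissingParameterError(CGStackError):
    """A force field lacks parameters for a declared bonded term."""


class DegenerateInputError(CGStackError):
    """Numerically degenerate input (zero variance, collinear plane, ...)."""


class EngineError(CGStackError):
    """Dynamics engine failure (non-finite coordinates/forces)."""
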