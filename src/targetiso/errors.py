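"""Exception hierarchy for targetiso.

All package errors derive from :class:`TargetIsoError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class TargetIsoError(Exception):
    """Base class for all targetiso errors."""


class GeneModelError(TargetIsoError):
    """A gene model violates a structural invariant (coordinates, a/b parts...)."""


class ParameterError(TargetIsoError, ValueError):
    """An operation received an out-of-range or unknown parameter."""


class ConfigError(TargetIsoError):
    """A simulation or pipeline configuration is inconsistent."""


class ClassificationError(TargetIsoError):
    """An isoform signature does not terminate in any recognized protein class."""


class NoOriginError(TargetIsoError):
    """An exon is absent from every species; no origin branch exists."""


class ParseError(TargetIsoError):
    """An input file could not be parsed.

    Carries file and line context where available.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)
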