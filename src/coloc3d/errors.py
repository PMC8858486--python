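"""Exception hierarchy for the co-localization pipeline.

All pipeline errors derive from :class:`Coloc3dError` so callers can catch
one base class; subclasses distinguish format problems, validation failures
and statistical preconditions.
"""


class Coloc3dError(Exception):
    """Base class for all package errors."""


class FormatError(Coloc3dError):
    """A file does not have the expected overall structure (missing columns,
    no parsable rows, unknown format name)."""


class ParseError(FormatError):
    """A specific row/line could not be parsed; carries the offending
    1-based line or row number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ValidationError(Coloc3dError):
    """Content parsed but violates an invariant (e.g. a chromosome with a
    single anchor, end < start)."""


class MappingError(Coloc3dError):
    """Feature placement on the 3D model failed (unknown chromosome, or no
    feature could be mapped at all)."""


class UnknownFeatureError(Coloc3dError, KeyError):
    """A feature id is absent from a distance-set index."""

    def __init__(self, feature_id: str):
        super().__init__(f"unknown feature id: {feature_id!r}")
        self.feature_id = feature_id


class ModuleTooSmallError(Coloc3dError):
    """Fewer than two module members matched the distance index, so no
    pairwise distance exists for the module."""

    def __init__(self, matched: int, unmatched: list[str] | None = None):
        super().__init__(
            f"module has {matched} matched member(s); at least 2 are required"
        )
        self.matched = matched
        self.unmatched = unmatched or []


class ParameterError(Coloc3dError):
    """A numeric parameter is out of its legal range."""


class InfeasibleModuleError(Coloc3dError):
    """No ball of the requested radius contains enough features to plant a
    module; reports the largest achievable size."""

    def __init__(self, requested: int, achievable: int, radius: float):
        super().__init__(
            f"cannot plant a module of {requested} features within radius "
            f"{radius}; largest achievable is {achievable}"
        )
        self.requested = requested
        self.achievable = achievable
        self.radius = radius
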