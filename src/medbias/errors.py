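"""Exception hierarchy shared across the package."""


class MedbiasError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MedbiasError):
    """A file could not be parsed in its declared dialect."""

    def __init__(self, message: str, *, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class BenchmarkValidationError(MedbiasError):
    """A benchmark dataset violates a structural invariant.

    ``codes`` carries machine-readable violation codes such as
    ``"overlapping-targets"`` or ``"duplicate-term"``.
    """

    def __init__(self, codes, messages=None):
        self.codes = list(codes)
        self.messages = list(messages) if messages is not None else list(codes)
        super().__init__("; ".join(self.messages))


class OOVError(MedbiasError):
    """A term's token is missing from the embedding vocabulary."""

    def __init__(self, token: str, term: str | None = None):
        self.token = token
        self.term = term
        msg = f"out-of-vocabulary token {token!r}"
        if term is not None and term != token:
            msg += f" (in term {term!r})"
        super().__init__(msg)


class DegenerateEmbeddingError(MedbiasError):
    """A zero vector appeared where a direction is required."""


class ZeroVarianceError(MedbiasError):
    """All association scores coincide; the effect size is undefined."""


class PoolTooSmallError(MedbiasError):
    """Attribute pool has fewer words than one draw requires."""


class DegenerateDrawsError(MedbiasError):
    """Resampling could not avoid zero-variance attribute draws."""
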