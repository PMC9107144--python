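"""Exception hierarchy shared across the package."""


class QtlModulesError(ValueError):
    """Base class for all package-specific errors."""


class SpecError(QtlModulesError):
    """A simulation spec or run configuration is internally inconsistent."""


class InputError(QtlModulesError):
    """Caller-supplied data violates a precondition (shapes, overlap, ranges)."""


class MonomorphicVariantError(InputError):
    """A dosage vector has zero variance, so slopes and r2 are undefined."""


class ParseError(QtlModulesError):
    """A text input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
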