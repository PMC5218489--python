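"""Exception types shared across the package."""


class PcrFidelityError(Exception):
    """Base class for package errors."""


class ConfigError(PcrFidelityError):
    """Invalid simulation or pipeline configuration.

    Carries a list of ``(path, reason)`` pairs naming each violated field.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [("", problems)]
        self.problems = list(problems)
        msg = "; ".join(f"{path}: {reason}" if path else reason
                        for path, reason in self.problems)
        super().__init__(msg)


class ConstraintError(PcrFidelityError):
    """Template construction constraints cannot be satisfied."""


class CoordinateError(PcrFidelityError):
    """A position lies outside the sequence it refers to."""


class MalformedReadError(PcrFidelityError):
    """A consensus read lacks required attributes (pass count, MAPQ, ...)."""


class UndefinedRateError(PcrFidelityError):
    """A rate is requested with a zero or invalid denominator."""
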