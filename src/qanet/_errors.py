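"""Exception hierarchy shared by all pipeline stages."""


class QanetError(Exception):
    """Base class for qanet errors."""


class ParameterError(QanetError, ValueError):
    """An argument value is outside its documented domain."""


class StructuralError(QanetError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""


class DegenerateScaleError(QanetError, ValueError):
    """A robust scale estimate collapsed to zero where that is fatal."""


class ValidationError(QanetError, ValueError):
    """A built object violates an enforced invariant (e.g. registry counts)."""


class MappingError(QanetError, KeyError):
    """A gene/species mapping refers to an unknown name."""


class SolverDivergenceError(QanetError, ArithmeticError):
    """The ODE trajectory became non-finite; try a smaller step."""


class FormatError(QanetError, ValueError):
    """A file does not parse as the expected format."""
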