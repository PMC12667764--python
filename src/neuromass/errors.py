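"""Exception types shared across the toolkit."""


class NeuromassError(Exception):
    """Base class for all package-specific errors."""


class ExpressionSyntaxError(NeuromassError):
    """Raised when an expression string cannot be parsed.

    Carries ``position``, a best-effort 0-based character offset into the
    original text.
    """

    def __init__(self, text: str, position: int, detail: str = ""):
        self.text = text
        self.position = position
        self.detail = detail
        super().__init__(
            f"syntax error at position {position} in {text!r}"
            + (f": {detail}" if detail else "")
        )


class UnknownSymbolError(NeuromassError):
    """Raised when an expression references a symbol outside the declared set."""

    def __init__(self, symbols, text: str = "", context: str = ""):
        self.symbols = sorted(str(s) for s in symbols)
        self.text = text
        self.context = context
        where = f" in equation for {context!r}" if context else ""
        super().__init__(
            f"unknown symbol(s) {', '.join(self.symbols)}{where}"
            + (f" in expression {text!r}" if text else "")
        )


class CycleError(NeuromassError):
    """Raised when a declared dependency structure contains a cycle."""

    def __init__(self, members, what="derived variables"):
        self.members = sorted(members)
        super().__init__(f"dependency cycle among {what}: {{{', '.join(self.members)}}}")


class NonDifferentiableError(NeuromassError):
    """Raised when a Jacobian entry involves a non-smooth construct."""

    def __init__(self, equation: str, construct: str):
        self.equation = equation
        self.construct = construct
        super().__init__(
            f"equation for {equation!r} contains non-differentiable construct "
            f"{construct!r}"
        )


class SpecValidationError(NeuromassError):
    """Raised by loaders when a specification fails validation.

    ``violations`` is the full list of Violation records so callers can report
    every problem at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"{v.code} at {v.path}: {v.message}" for v in self.violations)
        super().__init__(f"specification invalid ({len(self.violations)} problem(s)): {lines}")


class UnknownModelError(NeuromassError):
    """Raised when a catalogue lookup fails; lists the available names."""

    def __init__(self, name, available):
        self.name = name
        self.available = sorted(available)
        super().__init__(
            f"unknown model {name!r}; available: {', '.join(self.available)}"
        )


class SimulationOverflowError(NeuromassError):
    """Raised when any state magnitude exceeds the engine's overflow bound."""

    def __init__(self, step: int, time_ms: float, bound: float):
        self.step = step
        self.time_ms = time_ms
        self.bound = bound
        super().__init__(
            f"numerical overflow (|state| > {bound:g}) at step {step} (t = {time_ms:g} ms)"
        )


class NotReportedError(NeuromassError):
    """Raised when execution requires a parameter whose value is marked missing."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(
            "parameter value(s) marked as not_reported; supply values before "
            f"execution: {', '.join(self.names)}"
        )
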