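"""Exception hierarchy for holenet."""


class HolenetError(Exception):
    """Base class for all holenet errors."""


class ValidationError(HolenetError, ValueError):
    """An argument violates a precondition (bad weight, k out of range, ...)."""


class UndefinedStatisticError(HolenetError, ValueError):
    """A statistic is undefined for this input (empty graph, isolated node)."""


class GraphFormatError(HolenetError, ValueError):
    """Malformed input for a graph file format; carries a location when known."""

    def __init__(self, message, *, line=None, element=None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if element is not None:
            loc.append(f"element {element!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.line = line
        self.element = element


class CapabilityError(HolenetError, ValueError):
    """A dialect or operation cannot express the requested graph."""


class ConfigurationError(HolenetError, ValueError):
    """Unknown dialect name or invalid dialect options."""
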