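"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model or configuration parameter is outside its valid range."""


class GenerationError(RuntimeError):
    """Random-graph construction failed (e.g. stub matching exhausted retries)."""


class ComplexityError(RuntimeError):
    """An analytic sum would exceed the configured compute budget."""


class BracketError(ValueError):
    """A bisection bracket does not straddle the sought transition."""


class InfeasibleError(RuntimeError):
    """The requested optimisation has an empty feasible set."""
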