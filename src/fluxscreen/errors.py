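"""Exception hierarchy shared across the pipeline."""


class FluxscreenError(Exception):
    """Base class for all fluxscreen errors."""


class ModelParseError(FluxscreenError):
    """A model file could not be parsed; the message names the offending record."""


class ModelValidationError(FluxscreenError):
    """A parsed model violates a structural invariant."""


class GPRSyntaxError(FluxscreenError):
    """A gene-protein-reaction rule could not be parsed."""


class InfeasibleModelError(FluxscreenError):
    """The LP over the given bounds has no feasible flux distribution."""


class ParameterError(FluxscreenError):
    """A caller-supplied parameter is outside its allowed range."""


class AlignmentError(FluxscreenError):
    """Two tables that must share an axis do not."""
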