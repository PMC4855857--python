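"""Exception hierarchy for the infarct-quantification pipeline."""


class EWAError(Exception):
    """Base class for all pipeline errors."""


class InputError(EWAError):
    """Malformed or insufficient user input."""


class GeometryError(EWAError):
    """Contour / mask geometry violates a precondition."""


class FitError(EWAError):
    """A model fit is underdetermined or collapsed."""


class DegenerateInputError(EWAError):
    """Input has no usable contrast or spread."""


class ThresholdError(EWAError):
    """No valid intensity threshold exists for the fitted mixture."""


class ConsistencyError(EWAError):
    """Internal invariant violated between pipeline stages."""
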