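"""Exception types shared across the package."""


class StabscanError(ValueError):
    """Base class for validation and modelling errors."""


class ValidationError(StabscanError):
    """An input table or object violates a structural invariant."""


class DegenerateTransitionError(StabscanError):
    """A signal curve shows no resolvable unfolding transition."""


class ConvergenceError(StabscanError):
    """An iterative solver failed to reach its tolerance."""
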