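"""Exception types used across the package."""


class ModelValidationError(ValueError):
    """A model document is internally inconsistent (bad reference, bad fraction ...)."""


class NonNormalizableError(ModelValidationError):
    """The flux-balance system at the all-ones state has no strictly positive solution."""

    def __init__(self, message, species=()):
        super().__init__(message)
        self.species = list(species)


class NonConvergenceError(RuntimeError):
    """The steady-state solver did not converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientDataError(ValueError):
    """A sampled signal is too short for the requested estimate."""


class EmptyScanError(RuntimeError):
    """Every increment of a parameter scan was skipped."""
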