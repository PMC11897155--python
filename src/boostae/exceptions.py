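"""Exceptions and warnings shared across the package."""


class ZeroVarianceError(ValueError):
    """A column has zero corrected sample standard deviation and cannot be standardized."""

    def __init__(self, column_id):
        self.column_id = column_id
        super().__init__(f"zero variance in column {column_id!r}; cannot standardize")


class DegeneratePseudoResponse(RuntimeError):
    """The (constrained) pseudo-response for a latent dimension is constant across cells.

    Raised when the raw negative gradient has zero spread, or when the
    residual of the disentanglement projection vanishes because the
    pseudo-response lies in the span of the other latent dimensions.
    Training code catches this and skips the dimension for the epoch.
    """


class NoInformativeCovariateWarning(UserWarning):
    """All boosting selection scores are exactly zero; the step is a no-op."""
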