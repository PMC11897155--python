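"""Componentwise likelihood-based L2 boosting with linear base learners.

The model assumes i.i.d. homoscedastic Gaussian responses with identity
link, so each boosting step reduces to a closed-form least-squares fit of
one covariate to the current residual.  With standardized covariates the
selection criterion (squared score over Fisher information) simplifies to
the squared inner product of each covariate with the residual, making the
procedure equivalent to componentwise gradient boosting with squared-error
loss and to forward stagewise linear regression.  The residual variance
cancels from both the selection criterion and the coefficient update and
is therefore never represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NoInformativeCovariateWarning, ZeroVarianceError

__all__ = [
    "StandardizedMatrix",
    "BoostingConfig",
    "BoostFitState",
    "standardize_columns",
    "zscore",
    "boost_step",
    "compl2boost",
]

#: tolerance on |sd - 1| accepted for a standardized column
STANDARDIZATION_TOL = 1e-6


@dataclass(frozen=True)
class StandardizedMatrix:
    """A cells x variables matrix whose columns are z-scored.

    Columns listed in ``rescaled_columns`` were multiplied by a scalar
    factor after standardization (used to damp noise variables in the
    simulation designs) and are exempt from the unit-variance invariant.
    """

    values: np.ndarray
    column_ids: tuple
    rescaled_columns: frozenset = frozenset()

    @property
    def shape(self):
        return self.values.shape


def zscore(v: np.ndarray) -> np.ndarray:
    """Standardize a vector to mean 0 and corrected (n-1) sd 1."""
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if not sd > 0:
        raise ZeroVarianceError("<vector>")
    return (v - v.mean()) / sd


def standardize_columns(X, column_ids=None) -> StandardizedMatrix:
    """Z-score every column of ``X`` using the corrected (n-1 denominator) sd.

    Raises :class:`ZeroVarianceError` naming the first offending column if
    any column is constant.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, p = X.shape
    if column_ids is None:
        column_ids = tuple(range(p))
    else:
        column_ids = tuple(column_ids)
        if len(column_ids) != p:
            raise ValueError("column_ids length does not match column count")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise ZeroVarianceError(column_ids[bad[0]])
    return StandardizedMatrix((X - mu) / sd, column_ids)


@dataclass
class BoostingConfig:
    """Step size epsilon in (0, 1) and number of boosting steps M >= 1."""

    step_size: float = 0.01
    n_steps: int = 1

    def __post_init__(self):
        if not 0.0 < self.step_size < 1.0:
            raise ValueError(f"step_size must lie in (0, 1), got {self.step_size}")
        if self.n_steps < 1 or int(self.n_steps) != self.n_steps:
            raise ValueError(f"n_steps must be a positive integer, got {self.n_steps}")


@dataclass
class BoostFitState:
    """Coefficients beta, accumulated linear predictor (offset) eta and the
    ordered history of selected column indices."""

    coefficients: np.ndarray
    offset: np.ndarray
    selected_history: list = field(default_factory=list)

    @classmethod
    def zeros(cls, n: int, p: int) -> "BoostFitState":
        return cls(np.zeros(p), np.zeros(n))


def boost_step(X: np.ndarray, y: np.ndarray, state: BoostFitState, step_size: float) -> BoostFitState:
    """One componentwise boosting step.

    Selects ``j* = argmax_j ((x^(j))' (y - eta))^2`` (ties broken toward the
    smallest index by exact floating-point comparison), computes the
    closed-form least-squares coefficient
    ``gamma = (x^(j*))' (y - eta) / (x^(j*))' x^(j*)`` and updates exactly
    one coefficient: ``beta_{j*} += eps * gamma``, ``eta += eps * gamma * x^(j*)``.

    If every score is exactly zero the residual is orthogonal to all
    covariates; the step is a no-op and a
    :class:`NoInformativeCovariateWarning` is issued.
    """
    X = np.asarray(X, dtype=float)
    residual = np.asarray(y, dtype=float) - state.offset
    inner = X.T @ residual
    scores = inner**2
    if not np.any(scores > 0):
        warnings.warn("all selection scores are zero; no informative covariate",
                      NoInformativeCovariateWarning, stacklevel=2)
        return state
    j = int(np.argmax(scores))
    col = X[:, j]
    gamma = inner[j] / (col @ col)
    state.coefficients[j] += step_size * gamma
    state.offset += step_size * gamma * col
    state.selected_history.append(j)
    return state


def compl2boost(X, y, config: BoostingConfig, state: BoostFitState | None = None) -> BoostFitState:
    """Run ``config.n_steps`` sequential boosting steps with persistent offset.

    ``y`` is mean-centered internally if it is not already.  Coefficients
    start at zero unless an existing ``state`` is supplied (the autoencoder
    passes in the accumulated coefficients of a latent dimension together
    with a fresh zero offset).
    """
    if isinstance(X, StandardizedMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = y.mean()
    if mu != 0.0:
        y = y - mu
    n, p = X.shape
    if state is None:
        state = BoostFitState.zeros(n, p)
    for _ in range(config.n_steps):
        boost_step(X, y, state, config.step_size)
    return state
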