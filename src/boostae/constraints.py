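"""Disentanglement constraint for the boosting selection criterion.

Before boosting a latent dimension, its standardized pseudo-response is
replaced by the standardized residual of an ordinary-least-squares fit
against the currently populated other latent dimensions.  Genes selected
for the dimension then carry information complementary to what the other
dimensions already encode.

A constraint is any callable ``(g_hat, Z, B, l) -> y_hat`` mapping the
standardized pseudo-response of dimension ``l`` to a modified target, so
alternative selection constraints can be plugged into the training engine
without changes to it.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegeneratePseudoResponse

__all__ = ["exclusion_set", "disentangled_residual", "disentanglement_constraint"]


def exclusion_set(B: np.ndarray, l: int) -> frozenset:
    """Indices excluded from the projection basis for dimension ``l``:
    ``l`` itself plus every dimension whose encoder weights are all zero.

    Zero-weight columns only occur in the first training epoch; excluding
    them avoids singular projection bases.
    """
    B = np.asarray(B)
    d = B.shape[1]
    if not 0 <= l < d:
        raise ValueError(f"dimension index {l} out of range for d={d}")
    zero_cols = np.flatnonzero(~np.any(B != 0, axis=0))
    return frozenset({l}) | frozenset(int(k) for k in zero_cols)


def disentangled_residual(g_hat: np.ndarray, Z: np.ndarray, I: frozenset) -> np.ndarray:
    """OLS-residualize ``g_hat`` against the latent columns not in ``I``.

    If ``I`` covers all dimensions (first update of the first epoch) the
    pseudo-response is returned unchanged.  Otherwise the least-squares
    projection onto the retained columns is subtracted and the residual is
    re-standardized.  The least-squares solve uses the SVD-based
    minimum-norm solution, which coincides with the normal-equations
    estimator whenever the basis has full column rank and stays
    well-defined otherwise.

    Raises :class:`DegeneratePseudoResponse` when the residual is (numerically)
    zero, i.e. ``g_hat`` lies in the span of the retained columns.
    """
    g_hat = np.asarray(g_hat, dtype=float)
    Z = np.asarray(Z, dtype=float)
    keep = [k for k in range(Z.shape[1]) if k not in I]
    if not keep:
        return g_hat.copy()
    Zk = Z[:, keep]
    alpha, *_ = np.linalg.lstsq(Zk, g_hat, rcond=None)
    resid = g_hat - Zk @ alpha
    sd = resid.std(ddof=1)
    if not sd > 1e-10 * max(1.0, float(np.abs(g_hat).max())):
        raise DegeneratePseudoResponse(
            "pseudo-response lies in the span of the other latent dimensions")
    return (resid - resid.mean()) / sd


def disentanglement_constraint(g_hat: np.ndarray, Z: np.ndarray, B: np.ndarray, l: int) -> np.ndarray:
    """Constraint hook combining :func:`exclusion_set` and
    :func:`disentangled_residual`."""
    return disentangled_residual(g_hat, Z, exclusion_set(B, l))
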