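"""Boosting autoencoder training engine.

The model couples a sparse linear encoder ``Z = X B`` (no bias, identity
activation) with a small nonlinear decoder.  The encoder is never touched
by gradient descent: in every epoch, each column of ``B`` is updated by a
single componentwise boosting step whose target is the standardized
negative gradient of the batch-mean reconstruction loss with respect to
that latent dimension (the "pseudo-response").  The decoder is a fixed
two-layer map ``x_hat = W2 tanh(W1 z + b1) + b2`` with hidden width equal
to the input dimensionality, trained by Adam on the mean squared error.

Because the decoder architecture is fixed, all gradients are computed in
closed form; tests verify them against finite differences.

Two training regimes are provided.  In *alternating* mode the pseudo-
responses are re-derived for every latent dimension in turn (the decoder
stays fixed within the epoch, and the latent representation is recomputed
after each dimension's update), followed by one decoder step.  In
*jointLoss* mode the boosting update for all dimensions is executed
inside the forward evaluation of a joint objective on one mini-batch, and
the decoder gradient step on that same batch respects the freshly updated
encoder weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .boosting import BoostFitState, BoostingConfig, compl2boost
from .exceptions import DegeneratePseudoResponse

__all__ = [
    "DecoderParams",
    "TrainConfig",
    "BAEResult",
    "init_decoder",
    "decode",
    "reconstruction_loss",
    "latent_pseudo_responses",
    "encoder_epoch_update",
    "train_bae",
    "encode",
    "register_activation",
]

# Registered activations: name -> (function, derivative).  The derivative
# must be nonzero at 0, otherwise the pseudo-responses vanish at the zero
# initialization of B and the encoder never leaves it.
_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2),
}


def register_activation(name: str, fn: Callable, deriv: Callable) -> None:
    """Register a decoder activation; rejected if its derivative vanishes at 0."""
    if deriv(0.0) == 0.0:
        raise ValueError(
            f"activation {name!r} has zero derivative at 0; pseudo-responses would vanish")
    _ACTIVATIONS[name] = (fn, deriv)


@dataclass
class DecoderParams:
    """Parameters of the 2-layer decoder ``W2 rho(W1 z + b1) + b2``.

    ``W1`` is (p, d), ``b1`` and ``b2`` are length p, ``W2`` is (p, p);
    the hidden width equals the number of input variables p.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    activation: str = "tanh"

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    def arrays(self):
        return [self.W1, self.b1, self.W2, self.b2]


def init_decoder(p: int, d: int, rng: np.random.Generator, activation: str = "tanh") -> DecoderParams:
    """Glorot-uniform weight initialization with zero biases."""

    def glorot(fan_out, fan_in):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    return DecoderParams(glorot(p, d), np.zeros(p), glorot(p, p), np.zeros(p), activation)


def _forward(Z: np.ndarray, params: DecoderParams):
    fn, _ = _ACTIVATIONS[params.activation]
    H = fn(Z @ params.W1.T + params.b1)
    return H, H @ params.W2.T + params.b2


def decode(Z: np.ndarray, params: DecoderParams) -> np.ndarray:
    """Row-wise application of the fixed 2-layer decoder map."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != params.W1.shape[1]:
        raise ValueError(
            f"latent dimension mismatch: Z has {Z.shape[1]} columns, W1 expects {params.W1.shape[1]}")
    return _forward(Z, params)[1]


def reconstruction_loss(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Mean over cells of the per-cell mean squared error across genes."""
    X = np.asarray(X, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    return float(np.mean((X - Xhat) ** 2))


def _gradients(X: np.ndarray, Z: np.ndarray, params: DecoderParams):
    """Closed-form gradients of the batch-mean reconstruction loss.

    Returns (decoder gradients in the order of ``params.arrays()``, dL/dZ).
    """
    fn, deriv = _ACTIVATIONS[params.activation]
    A = Z @ params.W1.T + params.b1
    H = fn(A)
    Xhat = H @ params.W2.T + params.b2
    n, p = X.shape
    dXhat = (2.0 / (n * p)) * (Xhat - X)
    dW2 = dXhat.T @ H
    db2 = dXhat.sum(axis=0)
    dH = dXhat @ params.W2
    dA = dH * deriv(A)
    dW1 = dA.T @ Z
    db1 = dA.sum(axis=0)
    dZ = dA @ params.W1
    return [dW1, db1, dW2, db2], dZ


# degenerate pseudo-response detection: sd below this (relative to the
# gradient magnitude) counts as constant across cells
_DEGENERATE_TOL = 1e-12


def _standardize_pseudo_response(g: np.ndarray) -> np.ndarray:
    sd = g.std(ddof=1)
    if not sd > _DEGENERATE_TOL * max(1.0, float(np.abs(g).max())):
        raise DegeneratePseudoResponse("raw gradient is constant across cells")
    return (g - g.mean()) / sd


def latent_pseudo_responses(X: np.ndarray, B: np.ndarray, params: DecoderParams):
    """Standardized negative gradients of the batch loss w.r.t. each latent column.

    Returns ``(G_hat, skipped)`` where ``G_hat`` is n x d (columns of
    skipped dimensions are NaN) and ``skipped`` lists dimensions whose raw
    gradient was constant across cells.
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    Z = X @ B
    _, dZ = _gradients(X, Z, params)
    G = -dZ
    d = B.shape[1]
    G_hat = np.full_like(G, np.nan)
    skipped = []
    for l in range(d):
        try:
            G_hat[:, l] = _standardize_pseudo_response(G[:, l])
        except DegeneratePseudoResponse:
            skipped.append(l)
    return G_hat, skipped


class Adam:
    """Minimal Adam optimizer over a list of parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = None
        self.v = None

    def step(self, arrays, grads):
        if self.m is None:
            self.m = [np.zeros_like(a) for a in arrays]
            self.v = [np.zeros_like(a) for a in arrays]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainConfig:
    """Hyperparameters of one BAE training run.

    Defaults follow the method's standard settings: one boosting step of
    size 0.01 per dimension and epoch, Adam learning rate 0.01.
    ``batch_size=None`` trains on the full data every epoch; otherwise one
    uniformly sampled batch of that size drives both the boosting and the
    decoder step.  With ``partition_batches=True`` each epoch instead
    iterates over a shuffled partition of the data into batches, applying
    the boosting several times per epoch (which raises the attainable
    number of nonzero encoder weights accordingly).
    """

    latent_dim: int
    n_epochs: int
    mode: str = "alternating"
    batch_size: Optional[int] = None
    learning_rate: float = 0.01
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    seed: int = 0
    constraint: Optional[Callable] = None
    partition_batches: bool = False
    activation: str = "tanh"

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")
        if self.mode not in ("alternating", "jointLoss"):
            raise ValueError(f"mode must be 'alternating' or 'jointLoss', got {self.mode!r}")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class BAEResult:
    """Trained encoder weights, decoder parameters and the per-epoch log."""

    B: np.ndarray
    decoder: DecoderParams
    history: list

    def encode(self, X: np.ndarray) -> np.ndarray:
        return encode(X, self.B)


def encode(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Latent representation ``Z = X B`` of (possibly unseen) data."""
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    if X.shape[1] != B.shape[0]:
        raise ValueError(f"shape mismatch: X has {X.shape[1]} genes, B has {B.shape[0]} rows")
    return X @ B


def _boost_dimension(Xb, B, l, target, boosting: BoostingConfig, records, epoch):
    n = Xb.shape[0]
    state = BoostFitState(B[:, l], np.zeros(n))
    before = B[:, l].copy()
    compl2boost(Xb, target, boosting, state=state)
    for j in state.selected_history:
        records.append({"epoch": epoch, "dimension": l, "gene": int(j),
                        "coefficient": float(B[j, l]), "delta": float(B[j, l] - before[j])})


def encoder_epoch_update(Xb, B, params, boosting: BoostingConfig,
                         constraint: Optional[Callable] = None,
                         epoch: int = 0, records: Optional[list] = None) -> np.ndarray:
    """One alternating-mode encoder sweep over all latent dimensions.

    For each dimension in order, the pseudo-response is derived from the
    current state (Z is recomputed after every dimension's update, decoder
    held fixed), optionally passed through the constraint hook, and used
    as the target of a single-step boosting fit with a fresh zero offset
    against the dimension's accumulated coefficients.  Degenerate
    dimensions are skipped and logged.
    """
    if records is None:
        records = []
    d = B.shape[1]
    for l in range(d):
        Z = Xb @ B
        _, dZ = _gradients(Xb, Z, params)
        g = -dZ[:, l]
        try:
            g_hat = _standardize_pseudo_response(g)
            target = constraint(g_hat, Z, B, l) if constraint is not None else g_hat
        except DegeneratePseudoResponse as exc:
            records.append({"epoch": epoch, "dimension": l, "gene": -1,
                            "coefficient": np.nan, "delta": np.nan,
                            "skipped": str(exc)})
            continue
        _boost_dimension(Xb, B, l, target, boosting, records, epoch)
    return B


def _joint_epoch_update(Xb, B, params, boosting, constraint, epoch, records):
    """jointLoss-mode encoder sweep: pseudo-responses for all dimensions are
    taken from a single gradient evaluation at the epoch's starting state;
    the constraint still sees the representation updated dimension by
    dimension."""
    G_hat, skipped = latent_pseudo_responses(Xb, B, params)
    for l in skipped:
        records.append({"epoch": epoch, "dimension": l, "gene": -1,
                        "coefficient": np.nan, "delta": np.nan,
                        "skipped": "raw gradient constant"})
    d = B.shape[1]
    for l in range(d):
        if l in skipped:
            continue
        Z = Xb @ B
        try:
            target = constraint(G_hat[:, l], Z, B, l) if constraint is not None else G_hat[:, l]
        except DegeneratePseudoResponse as exc:
            records.append({"epoch": epoch, "dimension": l, "gene": -1,
                            "coefficient": np.nan, "delta": np.nan,
                            "skipped": str(exc)})
            continue
        _boost_dimension(Xb, B, l, target, boosting, records, epoch)
    return B


def train_bae(X: np.ndarray, config: TrainConfig,
              init_B: Optional[np.ndarray] = None,
              decoder: Optional[DecoderParams] = None) -> BAEResult:
    """Train a boosting autoencoder on standardized data.

    All randomness (decoder initialization, batch sampling) flows from
    ``config.seed``.  ``init_B`` allows warm-starting the encoder (used by
    the time-series extension); by default the encoder starts at zero.
    Returns the trained encoder weights, decoder parameters, and a
    per-epoch history of losses and selections.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    d = config.latent_dim
    if d >= p:
        raise ValueError(f"latent_dim ({d}) must be smaller than the number of genes ({p})")
    if config.batch_size is not None and config.batch_size > n:
        raise ValueError(f"batch_size ({config.batch_size}) exceeds number of cells ({n})")

    rng = np.random.default_rng(config.seed)
    if decoder is None:
        decoder = init_decoder(p, d, rng, config.activation)
    B = np.zeros((p, d)) if init_B is None else np.array(init_B, dtype=float)
    if B.shape != (p, d):
        raise ValueError(f"init_B has shape {B.shape}, expected {(p, d)}")

    adam = Adam(config.learning_rate)
    sweep = encoder_epoch_update if config.mode == "alternating" else None
    history = []
    for epoch in range(config.n_epochs):
        if config.batch_size is None:
            batches = [np.arange(n)]
        elif config.partition_batches:
            perm = rng.permutation(n)
            batches = [perm[i:i + config.batch_size] for i in range(0, n, config.batch_size)]
        else:
            batches = [rng.choice(n, size=config.batch_size, replace=False)]
        records: list = []
        for idx in batches:
            Xb = X[idx]
            if sweep is not None:
                encoder_epoch_update(Xb, B, decoder, config.boosting,
                                     config.constraint, epoch, records)
            else:
                _joint_epoch_update(Xb, B, decoder, config.boosting,
                                    config.constraint, epoch, records)
            grads, _ = _gradients(Xb, Xb @ B, decoder)
            adam.step(decoder.arrays(), grads)
        loss = reconstruction_loss(X, decode(X @ B, decoder))
        history.append({"epoch": epoch, "loss": loss, "selections": records})
    return BAEResult(B, decoder, history)
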