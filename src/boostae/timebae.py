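"""Time-series extension: one BAE per time point with delta pre-training.

One autoencoder is trained per time point, all with the same number of
latent dimensions d and the disentanglement constraint.  The encoder at
time t is initialized at the running delta
``B_tilde^(t+1) = B^(t) - B_tilde^(t)`` (with ``B_tilde^(1) = 0``) of the
previous training runs, while decoders are freshly randomized per time
point.  The deltas isolate what each time point's training added, and
initializing from them biases selection toward genes linked to the same
latent dimension before — coupling the dimension to the same
developmental trajectory across time.  The final encoder concatenates the
deltas ``B = (B_tilde^(2), ..., B_tilde^(T+1))``; a permuted variant
groups the T columns of each trajectory together.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .bae import BAEResult, TrainConfig, train_bae
from .constraints import disentanglement_constraint

__all__ = [
    "TimeBAEResult",
    "train_timebae",
    "zero_init_baseline",
    "concat_and_permute",
    "permutation_indices",
]


@dataclass
class TimeBAEResult:
    """Per-time-point trained matrices B^(t), the initialization deltas
    B_tilde^(1..T+1), the concatenated encoder B_full (p x d*T), its
    trajectory-grouped permutation B_perm, and the column mapping."""

    B_trained: list
    B_init: list
    B_full: np.ndarray
    B_perm: np.ndarray
    permutation: tuple
    histories: list

    @property
    def d(self) -> int:
        return self.B_trained[0].shape[1]

    @property
    def T(self) -> int:
        return len(self.B_trained)


def permutation_indices(d: int, T: int) -> tuple:
    """Column mapping from time-blocked order (all dims at t=1, then t=2, ...)
    to trajectory-blocked order (dim 1 at t=1..T, dim 2 at t=1..T, ...)."""
    return tuple(t * d + l for l in range(d) for t in range(T))


def _sub_seeds(master_seed: int, T: int):
    """Deterministic per-time-point seeds spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(T)]


def _run(matrices: Sequence[np.ndarray], config: TrainConfig, zero_init: bool) -> TimeBAEResult:
    if len(matrices) < 2:
        raise ValueError("time-series training needs at least two time points")
    mats = [np.asarray(X, dtype=float) for X in matrices]
    p = mats[0].shape[1]
    for t, X in enumerate(mats):
        if X.shape[1] != p:
            raise ValueError(
                f"inconsistent gene sets: time point {t + 1} has {X.shape[1]} genes, expected {p}")
    if config.constraint is None:
        config = replace(config, constraint=disentanglement_constraint)
    T = len(mats)
    d = config.latent_dim
    seeds = _sub_seeds(config.seed, T)
    B_init = [np.zeros((p, d))]
    B_trained, histories = [], []
    for t in range(T):
        cfg_t = replace(config, seed=seeds[t])
        start = np.zeros((p, d)) if zero_init else B_init[t].copy()
        res: BAEResult = train_bae(mats[t], cfg_t, init_B=start)
        B_trained.append(res.B)
        histories.append(res.history)
        B_init.append(res.B - B_init[t])
    B_full = np.hstack(B_init[1:])
    perm = permutation_indices(d, T)
    return TimeBAEResult(B_trained, B_init, B_full, B_full[:, list(perm)], perm, histories)


def train_timebae(matrices: Sequence[np.ndarray], config: TrainConfig) -> TimeBAEResult:
    """Sequential per-time-point training with delta-initialized encoders.

    ``matrices`` are the standardized per-time-point cells x genes
    matrices (cell counts may differ; gene sets must match).  The
    disentanglement constraint is used unless the config supplies another
    one.  One master seed spawns deterministic per-time-point sub-seeds.
    """
    return _run(matrices, config, zero_init=False)


def zero_init_baseline(matrices: Sequence[np.ndarray], config: TrainConfig) -> TimeBAEResult:
    """Ablation control: identical pipeline but every time point's encoder
    starts from zero, removing the cross-time coupling."""
    return _run(matrices, config, zero_init=True)


def concat_and_permute(result: TimeBAEResult):
    """Return (B_full, B_perm, mapping): the time-blocked concatenation and the
    trajectory-grouped column order with its explicit index mapping."""
    return result.B_full, result.B_perm, result.permutation
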