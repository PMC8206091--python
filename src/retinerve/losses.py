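"""Weighted multi-task training losses.

The visual-field loss is a doubly weighted sum of squared errors

    L_VF = sum_i lambda_i sum_j rho_j (y_ij - yhat_ij)^2

with per-record weights lambda_i counteracting the long-tailed severity
distribution and per-location weights rho_j emphasizing points near
fixation.  The MD loss is L_MD = sum_i lambda_i (z_i - zhat_i)^2, and the
total training objective blends them convexly:

    L = (1 - beta) L_VF + beta L_MD.

Weights:

    lambda_i = (1 - alpha) / N + alpha / (4 N_{I(i)})

where I(i) is the MD interval (1..4) of record i and N_k the number of
training records in interval k -- alpha = 0 is plain 1/N weighting, alpha = 1
equalizes the four intervals; and

    rho_j = exp(-d_j^2 / 2 gamma^2) / sum_k exp(-d_k^2 / 2 gamma^2)

a normalized Gaussian in the center distance d_j, flat as gamma -> inf.
Both weight vectors sum to one (exactly, when all four intervals are
populated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .vf_geometry import VFGrid, interval_of

__all__ = [
    "LossConfig",
    "location_weights",
    "sample_weights",
    "vf_loss",
    "md_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """(alpha, beta, gamma) of the weighted multi-task objective.

    alpha, beta in [0, 1]; gamma > 0.  (alpha=0, beta=0) is the basic,
    single-task, uniformly weighted model.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


def location_weights(grid: VFGrid, gamma: float) -> np.ndarray:
    """rho_j over the 52 locations: softmax of -d_j^2 / (2 gamma^2)."""
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    d = grid.distances
    logits = -(d**2) / (2.0 * gamma**2)
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def sample_weights(md: "Iterable[float] | np.ndarray", alpha: float) -> np.ndarray:
    """lambda_i for each record from its (true) MD value.

    Raises if alpha > 0 and some MD interval is unpopulated, since the
    per-interval term divides by the interval count.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    md = np.asarray(list(md) if not isinstance(md, np.ndarray) else md, dtype=float)
    n = md.size
    if n == 0:
        raise ValueError("empty dataset")
    ids = np.array([interval_of(m) for m in md])
    counts = {k: int((ids == k).sum()) for k in (1, 2, 3, 4)}
    if alpha > 0:
        empty = [k for k, c in counts.items() if c == 0]
        if empty:
            raise ValueError(
                f"alpha={alpha} > 0 requires all four MD intervals populated; "
                f"empty interval(s): {empty}"
            )
    lam = np.full(n, (1.0 - alpha) / n)
    if alpha > 0:
        per = np.array([alpha / (4.0 * counts[k]) for k in ids])
        lam = lam + per
    return lam


def _check_shapes(y_true: np.ndarray, y_hat: np.ndarray) -> None:
    if y_true.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_hat.shape}")


def vf_loss(y_true: np.ndarray, y_hat: np.ndarray,
            lambdas: np.ndarray, rhos: np.ndarray) -> float:
    """Doubly weighted sum of squared pointwise errors (no extra averaging)."""
    y_true = np.asarray(y_true, float)
    y_hat = np.asarray(y_hat, float)
    _check_shapes(y_true, y_hat)
    lambdas = np.asarray(lambdas, float)
    rhos = np.asarray(rhos, float)
    if lambdas.shape != (y_true.shape[0],) or rhos.shape != (y_true.shape[1],):
        raise ValueError("weight shapes do not match data")
    sq = (y_true - y_hat) ** 2
    return float(lambdas @ sq @ rhos)


def md_loss(z_true: np.ndarray, z_hat: np.ndarray, lambdas: np.ndarray) -> float:
    """lambda-weighted sum of squared MD errors."""
    z_true = np.asarray(z_true, float)
    z_hat = np.asarray(z_hat, float)
    _check_shapes(z_true, z_hat)
    return float(np.asarray(lambdas, float) @ (z_true - z_hat) ** 2)


def total_loss(vf: float, md: float, beta: float) -> float:
    """Convex blend (1 - beta) * L_VF + beta * L_MD."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    return (1.0 - beta) * vf + beta * md
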