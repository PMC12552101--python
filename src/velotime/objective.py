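"""Loss terms of the joint objective.

All terms are written as log-likelihood-style quantities (<= 0), summed
over features and *averaged per cell* so the objective magnitude does
not depend on batch size.  The trainer maximizes

    L = (Lt1 + Lt2 + Lt3) + lambda_v * (Lv1 + Lv2)

by minimizing -L.

Lt1  weighted reconstruction error of X from Z and from Zt;
Lt2  negative KL divergence between the posterior N(mu, sigma^2 I) and
     the standard-normal prior;
Lt3  negative squared distance between Z and Zt;
Lv1  negative squared error of the Euler reconstruction of (S, U);
Lv2  penalty driving unspliced velocity to zero on the entries whose
     total expression exceeds a high per-gene percentile (near-
     saturation cells are expected to be kinetically stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .errors import ConfigError, DataError

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "loss_reconstruction",
    "loss_kl",
    "loss_latent_consistency",
    "loss_velocity_reconstruction",
    "omega_mask",
    "loss_unspliced_penalty",
    "total_objective",
]


@dataclass
class LossWeights:
    omega: float = 0.5
    lambda_v: float = 1.0
    q_omega: float = 95.0

    def __post_init__(self):
        if not (0.0 < self.omega < 1.0):
            raise ConfigError("omega must be in (0, 1)")
        if self.lambda_v < 0:
            raise ConfigError("lambda_v must be >= 0")
        if not (0.0 < self.q_omega < 100.0):
            raise ConfigError("q_omega must be in (0, 100)")


@dataclass
class LossBreakdown:
    lt1: float
    lt2: float
    lt3: float
    lv1: float
    lv2: float
    total: float


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _check_same_shape(a, b):
    sa = a.shape if not isinstance(a, Tensor) else a.data.shape
    sb = b.shape if not isinstance(b, Tensor) else b.data.shape
    if sa != sb:
        raise DataError(f"shape-mismatch: {sa} vs {sb}")


def _n_cells(x) -> int:
    shape = x.data.shape if isinstance(x, Tensor) else np.shape(x)
    return shape[0] if len(shape) > 0 else 1


def _neg_sq_per_cell(diff: Tensor, n: int) -> Tensor:
    return (diff * diff).sum() * (-1.0 / n)


def loss_reconstruction(X, Xhat_n, Xhat_t, omega: float) -> Tensor:
    """Lt1: weighted reconstruction error of the two latent paths."""
    _check_same_shape(X, Xhat_n)
    _check_same_shape(X, Xhat_t)
    n = _n_cells(X)
    X = np.asarray(X.data if isinstance(X, Tensor) else X, dtype=float)
    err_n = _neg_sq_per_cell(_as_t(Xhat_n) - X, n)
    err_t = _neg_sq_per_cell(_as_t(Xhat_t) - X, n)
    return err_n * omega + err_t * (1.0 - omega)


def loss_kl(mu, log_sigma2) -> Tensor:
    """Lt2 = -KL(N(mu, diag sigma^2) || N(0, I)), averaged per cell."""
    mu = _as_t(mu)
    log_sigma2 = _as_t(log_sigma2)
    _check_same_shape(mu, log_sigma2)
    n = _n_cells(mu)
    kl = (mu * mu + log_sigma2.exp() - 1.0 - log_sigma2).sum() * (0.5 / n)
    return kl * (-1.0)


def loss_latent_consistency(Z, Zt) -> Tensor:
    """Lt3: negative squared distance between sampled and evolved states."""
    _check_same_shape(Z, Zt)
    return _neg_sq_per_cell(_as_t(Z) - _as_t(Zt), _n_cells(Z))


def loss_velocity_reconstruction(Xsu, Xhat_su) -> Tensor:
    """Lv1: negative squared error of the Euler reconstruction."""
    _check_same_shape(Xsu, Xhat_su)
    Xsu = np.asarray(Xsu.data if isinstance(Xsu, Tensor) else Xsu, float)
    return _neg_sq_per_cell(_as_t(Xhat_su) - Xsu, Xsu.shape[0])


def omega_mask(S: np.ndarray, U: np.ndarray, q: float = 95.0) -> np.ndarray:
    """Entries whose total expression strictly exceeds the per-gene
    q-th percentile of S + U (linear-interpolation percentile)."""
    S = np.asarray(S, dtype=float)
    U = np.asarray(U, dtype=float)
    _check_same_shape(S, U)
    total = S + U
    thresh = np.percentile(total, q, axis=0, method="linear")
    return total > thresh


def loss_unspliced_penalty(Vu, mask: np.ndarray) -> Tensor:
    """Lv2: squared unspliced velocity summed over the masked entries."""
    Vu_t = _as_t(Vu)
    _check_same_shape(Vu_t, Tensor(mask.astype(float)))
    n = _n_cells(Vu_t)
    masked = Vu_t * mask.astype(float)
    return (masked * masked).sum() * (-1.0 / n)


def total_objective(lt1, lt2, lt3, lv1, lv2, weights: LossWeights):
    """Combine terms into L = Lt + lambda_v * Lv.

    Returns (total tensor to maximize, LossBreakdown of float values).
    """
    total = lt1 + lt2 + lt3 + (lv1 + lv2) * weights.lambda_v
    bd = LossBreakdown(
        lt1=float(lt1.item() if isinstance(lt1, Tensor) else lt1),
        lt2=float(lt2.item() if isinstance(lt2, Tensor) else lt2),
        lt3=float(lt3.item() if isinstance(lt3, Tensor) else lt3),
        lv1=float(lv1.item() if isinstance(lv1, Tensor) else lv1),
        lv2=float(lv2.item() if isinstance(lv2, Tensor) else lv2),
        total=float(total.item() if isinstance(total, Tensor) else total),
    )
    return total, bd
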