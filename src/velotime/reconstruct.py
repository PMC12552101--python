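"""Segmented Euler reconstruction of (S, U) along pseudotime.

Cells are sorted by pseudotime and partitioned into consecutive
segments of length `interval_l`.  Within each segment the first cell's
reconstruction is pinned to its observation; each subsequent cell is
predicted from the previous one's *running estimate* by one Euler step
of the kinetic ODEs, with the transcription rate taken at the previous
cell's latent state.  Restarting every `interval_l` cells bounds the
accumulated first-order error.  Negative running estimates are not
clipped: the reconstruction loss is allowed to penalize them.

All segments advance in lockstep (one vectorized Euler step per sorted
position), so the tape length grows with the segment length, not with
the number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from ._autodiff import Tensor, concat
from .errors import ConfigError, DataError
from .model import ModelState, transcription_rate

__all__ = ["EulerConfig", "segment_by_time", "euler_reconstruct"]


@dataclass
class EulerConfig:
    interval_l: int = 50
    # evaluate step velocities at the observed expression of the previous
    # cell instead of its running estimate (off: literal recursion)
    use_observed: bool = False

    def __post_init__(self):
        if self.interval_l < 2:
            raise ConfigError("interval_l must be >= 2")


def segment_by_time(t, interval_l: int) -> List[np.ndarray]:
    """Partition cells into time-consecutive segments of original indices.

    Cells are stably sorted by t (ties broken by original index) and
    chunked into segments of `interval_l`; a leftover singleton is
    merged into the previous segment so every segment has >= 2 cells.
    """
    tvals = t.data if isinstance(t, Tensor) else np.asarray(t, dtype=float)
    if not np.all(np.isfinite(tvals)):
        raise DataError("non-finite pseudotime")
    n = len(tvals)
    if n < 2:
        raise DataError("too-few-cells")
    order = np.argsort(tvals, kind="stable")
    bounds = list(range(0, n, interval_l))
    segments = [order[b:b + interval_l] for b in bounds]
    if len(segments) > 1 and len(segments[-1]) == 1:
        segments[-2] = np.concatenate([segments[-2], segments[-1]])
        segments.pop()
    return segments


def euler_reconstruct(Xsu: np.ndarray, t, Zt: Tensor, state: ModelState,
                      cfg: Optional[EulerConfig] = None,
                      alpha: Optional[Tensor] = None) -> Tensor:
    """Reconstruct the observed (S, U) matrix along pseudotime.

    Parameters
    ----------
    Xsu
        Observed n x 2p matrix with spliced columns first.
    t
        Per-cell pseudotime (Tensor or array, original cell order).
        When a Tensor, gradients flow through the time increments.
    Zt
        ODE-evolved latent states, original cell order.
    alpha
        Optional precomputed transcription rates (n x p); computed from
        `Zt` when omitted.

    Returns the n x 2p reconstruction in the original cell order.
    """
    cfg = cfg or EulerConfig()
    Xsu = np.asarray(Xsu, dtype=np.float64)
    n = Xsu.shape[0]
    p = state.n_genes
    if Xsu.shape[1] != 2 * p:
        raise DataError("shape-mismatch: Xsu must have 2 * n_genes columns")
    if Zt.shape[0] != n:
        raise DataError("shape-mismatch: Zt rows != cells")
    t_t = t if isinstance(t, Tensor) else Tensor(np.asarray(t, dtype=float))
    if alpha is None:
        alpha = transcription_rate(state, Zt)

    beta = state.log_beta.exp()
    gamma = state.log_gamma.exp()

    segments = segment_by_time(t_t, cfg.interval_l)
    starts = np.array([seg[0] for seg in segments])
    sizes = np.array([len(seg) for seg in segments])

    rows_idx = [starts]
    S_run = Tensor(Xsu[starts, :p])
    U_run = Tensor(Xsu[starts, p:])
    rows_S = [S_run]
    rows_U = [U_run]

    active = np.arange(len(segments))
    for j in range(1, sizes.max()):
        keep = sizes[active] > j
        if not keep.all():
            pos = np.flatnonzero(keep)
            S_run = S_run.take(pos)
            U_run = U_run.take(pos)
            active = active[keep]
        prev_idx = np.array([segments[s][j - 1] for s in active])
        cur_idx = np.array([segments[s][j] for s in active])
        dt = (t_t.take(cur_idx) - t_t.take(prev_idx)).reshape(-1, 1)
        a_prev = alpha.take(prev_idx)
        if cfg.use_observed:
            S_prev = Tensor(Xsu[prev_idx, :p])
            U_prev = Tensor(Xsu[prev_idx, p:])
        else:
            S_prev, U_prev = S_run, U_run
        Vu = a_prev - beta * U_prev
        Vs = beta * U_prev - gamma * S_prev
        S_run = S_run + Vs * dt
        U_run = U_run + Vu * dt
        rows_idx.append(cur_idx)
        rows_S.append(S_run)
        rows_U.append(U_run)

    all_idx = np.concatenate(rows_idx)
    Xhat = concat([concat(rows_S, axis=0), concat(rows_U, axis=0)], axis=1)
    return Xhat.take(np.argsort(all_idx, kind="stable"))
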