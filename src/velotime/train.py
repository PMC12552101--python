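"""Mini-batch training, direction correction and prediction.

:func:`fit` runs the full procedure on a preprocessed dataset: seeded
mini-batch optimization of the joint objective, an evaluation-mode
forward pass, the Pearson direction correction (flipping pseudotime and
velocity together when the spliced velocity correlates the wrong way
with U and S), and a velocity-pseudotime consistency check that
triggers at most one retrain from a time-reversed initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from ._autodiff import Tensor, no_grad
from ._nn import Adam
from .data_io import OmicsDataset, knn_indices
from .errors import ConfigError, DataError, TrainingError
from .model import (LatentOutputs, ModelConfig, ModelState, VelocityEstimate,
                    compute_velocity, decode, encode, init_model,
                    integrate_latent, transcription_rate)
from .objective import (LossBreakdown, LossWeights, loss_kl,
                        loss_latent_consistency, loss_reconstruction,
                        loss_unspliced_penalty, loss_velocity_reconstruction,
                        omega_mask, total_objective)
from .reconstruct import EulerConfig, euler_reconstruct

__all__ = [
    "TrainConfig",
    "FitResult",
    "fit",
    "predict",
    "flip_orientation",
    "direction_correction",
    "velocity_pseudotime_check",
]


@dataclass
class TrainConfig:
    batch_size: int = 1024
    epochs: int = 400
    lr: float = 0.01
    weight_decay: float = 0.01
    adam_eps: float = 0.01
    amsgrad: bool = True
    lambda_u: float = 0.5
    lambda_s: float = 0.5
    seed: int = 0
    early_stop_patience: int = 30

    def __post_init__(self):
        if self.batch_size < 2:
            raise ConfigError("batch_size must be >= 2")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        for name in ("lambda_u", "lambda_s"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must be in (0, 1)")


@dataclass
class FitResult:
    """Outputs of a completed fit.

    `t_raw` is the (orientation-signed) pre-sigmoid time-encoder output;
    `t = sigmoid(t_raw)`.  Direction flips negate `t_raw`, so flipping
    is an exact involution.
    """

    model: ModelState
    t: np.ndarray
    t_raw: np.ndarray
    velocity: VelocityEstimate
    Zt: np.ndarray
    flipped: bool
    retrained: bool
    l_pearson: float
    vpt_corr: float
    loss_history: List[LossBreakdown] = field(default_factory=list)


def flip_orientation(result: FitResult) -> FitResult:
    """Reverse pseudotime and velocity direction (t -> 1 - t, V -> -V).

    The time flip acts on the pre-sigmoid output (1 - sigmoid(x) =
    sigmoid(-x)), so applying the flip twice restores the original
    arrays bit-exactly.
    """
    from scipy.special import expit

    vel = result.velocity
    return FitResult(
        model=result.model,
        t=expit(-result.t_raw),
        t_raw=-result.t_raw,
        velocity=VelocityEstimate(alpha=vel.alpha,
                                  Vu=-np.asarray(vel.Vu),
                                  Vs=-np.asarray(vel.Vs)),
        Zt=result.Zt,
        flipped=not result.flipped,
        retrained=result.retrained,
        l_pearson=result.l_pearson,
        vpt_corr=result.vpt_corr,
        loss_history=result.loss_history,
    )


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------

def _batch_indices(n: int, batch_size: int,
                   rng: np.random.Generator) -> List[np.ndarray]:
    perm = rng.permutation(n)
    batches = [perm[i:i + batch_size] for i in range(0, n, batch_size)]
    # a trailing batch of < 4 cells is merged (segmentation needs >= 2,
    # the losses are more stable with a few more)
    if len(batches) > 1 and len(batches[-1]) < 4:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def _train_once(X: np.ndarray, S: np.ndarray, U: np.ndarray,
                mcfg: ModelConfig, weights: LossWeights, tcfg: TrainConfig,
                ecfg: EulerConfig, reverse_time: bool
                ) -> Tuple[ModelState, List[LossBreakdown]]:
    n, m = X.shape
    p = S.shape[1]
    state = init_model(mcfg, p, m, reverse_time=reverse_time)
    opt = Adam(state.parameters(), lr=tcfg.lr, eps=tcfg.adam_eps,
               weight_decay=tcfg.weight_decay, amsgrad=tcfg.amsgrad)
    rng = np.random.default_rng(tcfg.seed)
    Xsu = np.concatenate([S, U], axis=1)

    history: List[LossBreakdown] = []
    best = np.inf
    stale = 0
    for epoch in range(tcfg.epochs):
        sums = np.zeros(6)
        wsum = 0.0
        for bidx in _batch_indices(n, min(tcfg.batch_size, n), rng):
            Xb = X[bidx]
            Sb, Ub = S[bidx], U[bidx]
            lat = encode(state, Xb, sample=True, rng=rng)
            order = lat.order
            Zt0 = lat.Z.take([order[0]])
            t_sorted = lat.t.take(order)
            Zt_sorted = integrate_latent(state, Zt0, t_sorted)
            inv = np.argsort(order, kind="stable")
            Zt = Zt_sorted.take(inv)

            Xhat_n = decode(state, lat.Z)
            Xhat_t = decode(state, Zt)
            lt1 = loss_reconstruction(Xb, Xhat_n, Xhat_t, weights.omega)
            lt2 = loss_kl(lat.mu, lat.log_sigma2)
            lt3 = loss_latent_consistency(lat.Z, Zt)

            alpha = transcription_rate(state, Zt)
            Xhat_su = euler_reconstruct(Xsu[bidx], lat.t, Zt, state, ecfg,
                                        alpha=alpha)
            lv1 = loss_velocity_reconstruction(Xsu[bidx], Xhat_su)
            mask = omega_mask(Sb, Ub, weights.q_omega)
            Vu = alpha - state.log_beta.exp() * Ub
            lv2 = loss_unspliced_penalty(Vu, mask)

            total, bd = total_objective(lt1, lt2, lt3, lv1, lv2, weights)
            if not np.isfinite(bd.total):
                raise TrainingError(f"training-diverged at epoch {epoch}")
            loss = total * (-1.0)
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = len(bidx)
            sums += w * np.array([bd.lt1, bd.lt2, bd.lt3, bd.lv1, bd.lv2,
                                  bd.total])
            wsum += w
        ep = sums / wsum
        history.append(LossBreakdown(*ep))
        neg_total = -ep[5]
        if neg_total < best - 1e-9:
            best = neg_total
            stale = 0
        else:
            stale += 1
            if stale >= tcfg.early_stop_patience:
                break
    return state, history


def _forward_eval(state: ModelState, X: np.ndarray):
    """Deterministic evaluation pass: pseudotime and evolved latents."""
    with no_grad():
        lat = encode(state, X, sample=False)
        order = lat.order
        Zt0 = lat.mu.take([order[0]])
        Zt_sorted = integrate_latent(state, Zt0, lat.t.take(order))
        Zt = Zt_sorted.take(np.argsort(order, kind="stable"))
        alpha = transcription_rate(state, Zt)
    return (lat.t.data.copy(), lat.t_raw.data.copy(), Zt.data.copy(),
            alpha.data.copy())


def predict(state: ModelState, ds: OmicsDataset
            ) -> Tuple[np.ndarray, VelocityEstimate, np.ndarray]:
    """Evaluation-mode pseudotime, velocities and latent states.

    Works on arbitrary (possibly unseen) cells whose feature layout
    matches the model; no sampling, no training.
    """
    X = ds.X
    if X.shape[1] != state.n_features:
        raise DataError(
            f"shape-mismatch: model expects {state.n_features} features, "
            f"dataset has {X.shape[1]}")
    t, _, Zt, alpha = _forward_eval(state, X)
    vel = compute_velocity(ds.U, ds.S, alpha, state.beta, state.gamma)
    return t, vel, Zt


# ----------------------------------------------------------------------
# direction correction & consistency check
# ----------------------------------------------------------------------

def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of A with the same row of B;
    NaN where either row is constant."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def direction_correction(Vs: np.ndarray, U: np.ndarray, S: np.ndarray,
                         lambda_u: float = 0.5, lambda_s: float = 0.5,
                         per_cell: bool = True) -> Tuple[bool, float]:
    """Pearson direction score and flip decision.

    Because Vs = beta*U - gamma*S, a correctly oriented velocity should
    correlate positively with U and negatively with S.  The score

        L = lambda_u * corr(Vs, U) - lambda_s * corr(Vs, S)

    is averaged over cells (correlations taken across genes); a
    negative score means pseudotime and velocity should be reversed
    (t -> 1 - t, V -> -V) by the caller.
    """
    Vs = np.asarray(Vs, float)
    U = np.asarray(U, float)
    S = np.asarray(S, float)
    if Vs.shape != U.shape or Vs.shape != S.shape:
        raise DataError("shape-mismatch")
    if per_cell:
        cu = _rowwise_pearson(Vs, U)
        cs = _rowwise_pearson(Vs, S)
        valid = ~(np.isnan(cu) | np.isnan(cs))
        if not valid.any():
            raise DataError("degenerate-correlation")
        if not valid.all():
            warnings.warn(f"{(~valid).sum()} cells with constant rows "
                          "skipped in direction correction")
        score = float(np.mean(lambda_u * cu[valid] - lambda_s * cs[valid]))
    else:
        cu = np.corrcoef(Vs.ravel(), U.ravel())[0, 1]
        cs = np.corrcoef(Vs.ravel(), S.ravel())[0, 1]
        if np.isnan(cu) or np.isnan(cs):
            raise DataError("degenerate-correlation")
        score = float(lambda_u * cu - lambda_s * cs)
    return score < 0, score


def velocity_pseudotime_check(t: np.ndarray, velocity: VelocityEstimate,
                              ds: OmicsDataset, knn_k: int = 30
                              ) -> Tuple[bool, float]:
    """Sign check between a velocity-derived pseudotime and `t`.

    A KNN graph is built on the (smoothed) spliced matrix; transition
    probabilities to neighbors are the softmax of the cosine similarity
    between a cell's spliced velocity and the expression displacement
    to the neighbor.  Iterating this operator from a uniform start
    yields a stationary-style score whose rank is the velocity
    pseudotime; consistency means it correlates nonnegatively with `t`.
    """
    S = ds.S
    Vs = np.asarray(velocity.Vs, float)
    n = len(t)
    if np.allclose(Vs, 0.0):
        warnings.warn("all velocities are zero; direction check skipped")
        return True, float("nan")
    k = min(knn_k, n - 1)
    nbrs = knn_indices(S, k + 1)[:, 1:]  # exclude self

    disp = S[nbrs] - S[:, None, :]                      # (n, k, p)
    vnorm = np.linalg.norm(Vs, axis=1, keepdims=True)
    dnorm = np.linalg.norm(disp, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("nkp,np->nk", disp, Vs) / (dnorm * vnorm + 1e-12)
    cos = np.nan_to_num(cos)
    ex = np.exp(cos - cos.max(axis=1, keepdims=True))
    P_data = ex / ex.sum(axis=1, keepdims=True)

    rows = np.repeat(np.arange(n), k)
    P = sparse.csr_matrix((P_data.ravel(), (rows, nbrs.ravel())),
                          shape=(n, n))
    sym = P + P.T
    n_comp, labels = connected_components(sym, directed=False)
    used = np.arange(n)
    if n_comp > 1:
        warnings.warn("KNN graph is disconnected; using largest component")
        largest = np.argmax(np.bincount(labels))
        used = np.flatnonzero(labels == largest)
        P = P[used][:, used]
        row_sums = np.asarray(P.sum(axis=1)).ravel()
        row_sums[row_sums == 0] = 1.0
        P = sparse.diags(1.0 / row_sums) @ P

    pi = np.full(len(used), 1.0 / len(used))
    for _ in range(1000):
        nxt = pi @ P
        if np.abs(nxt - pi).max() < 1e-8:
            pi = nxt
            break
        pi = nxt
    vpt = (rankdata(pi, method="average") - 1) / max(len(used) - 1, 1)
    tt = np.asarray(t, float)[used]
    if np.std(vpt) == 0 or np.std(tt) == 0:
        warnings.warn("degenerate velocity pseudotime; treated as consistent")
        return True, float("nan")
    corr = float(np.corrcoef(vpt, tt)[0, 1])
    return corr >= 0, corr


# ----------------------------------------------------------------------
# fit
# ----------------------------------------------------------------------

def fit(ds: OmicsDataset, mcfg: Optional[ModelConfig] = None,
        weights: Optional[LossWeights] = None,
        tcfg: Optional[TrainConfig] = None,
        ecfg: Optional[EulerConfig] = None,
        direction_check: bool = True,
        reverse_init: bool = False) -> FitResult:
    """Train on a preprocessed dataset and produce final estimates.

    After optimization a deterministic evaluation pass computes
    pseudotime, latent states and velocities at the observed (smoothed)
    expression; the Pearson direction correction may flip (t, V), and a
    failed velocity-pseudotime consistency check triggers one retrain
    from a time-reversed initialization.
    """
    mcfg = mcfg or ModelConfig()
    weights = weights or LossWeights()
    tcfg = tcfg or TrainConfig()
    ecfg = ecfg or EulerConfig()
    if ds.n_cells < 4:
        raise DataError("too-few-cells: need at least 4")

    X = ds.X

    def run(reverse_time: bool) -> FitResult:
        state, history = _train_once(X, ds.S, ds.U, mcfg, weights, tcfg,
                                     ecfg, reverse_time)
        t, t_raw, Zt, alpha = _forward_eval(state, X)
        vel = compute_velocity(ds.U, ds.S, alpha, state.beta, state.gamma)
        res = FitResult(model=state, t=t, t_raw=t_raw, velocity=vel, Zt=Zt,
                        flipped=False, retrained=False,
                        l_pearson=float("nan"), vpt_corr=float("nan"),
                        loss_history=history)
        if direction_check:
            try:
                flip, lp = direction_correction(np.asarray(vel.Vs), ds.U,
                                                ds.S, tcfg.lambda_u,
                                                tcfg.lambda_s)
            except DataError:
                flip, lp = False, float("nan")
            if flip:
                res = flip_orientation(res)
            res.l_pearson = lp
        return res

    res = run(reverse_time=reverse_init)
    if direction_check and tcfg.epochs > 0:
        consistent, vpt_corr = velocity_pseudotime_check(res.t, res.velocity,
                                                         ds)
        if not consistent:
            res = run(reverse_time=not reverse_init)
            res.retrained = True
            _, vpt_corr = velocity_pseudotime_check(res.t, res.velocity, ds)
        res.vpt_corr = vpt_corr
    return res
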