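"""Benchmark simulators with known transcription kinetics.

Each gene follows the two-ODE splicing model

    dU/dt = alpha_g(t) - beta_g * U,      dS/dt = beta_g * U - gamma_g * S,

with constant per-gene splicing (beta) and degradation (gamma) rates and
a transcription rate alpha that varies along a latent developmental
time.  Two trajectory topologies are provided: a *linear* trajectory
where alpha follows a gene-specific sigmoid switch (half the genes
increasing, half decreasing), and a *circular* trajectory where each
gene is induced on an arc of the unit circle and repressed elsewhere,
integrated past burn-in so cells sit on the limit cycle.  The circular
simulator can attach an accessibility-like second modality whose
features open slightly before each gene's induction arc.

Perturbation protocols used in robustness studies are included:
binomial thinning (read loss), joint depth down-sampling (multivariate
hypergeometric) and removal of a labeled cell population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.special import expit

from .data_io import OmicsDataset
from .errors import ConfigError, DataError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_linear",
    "simulate_circular",
    "simulate_dataset",
    "binomial_thinning",
    "downsample_depth",
    "remove_cell_type",
]

_RK4_STEP = 1e-3
# the slowest degradation rates are ~e^-0.2 per period, so several
# periods of burn-in are needed before the spliced transient (~e^{-gamma k})
# is negligible and sampled cells sit on the limit cycle
_BURN_IN_PERIODS = 8
_MODALITY_LEAD = 0.05
_MODALITY_EDGE = 0.02


@dataclass
class SimulationConfig:
    n_cells: int
    n_genes: int
    topology: str = "linear"
    noise_sd: float = 0.1
    with_modality: bool = False
    seed: int = 0
    rate_sd: float = 0.1

    def __post_init__(self):
        if self.n_cells < 2:
            raise ConfigError("n_cells must be >= 2")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.topology not in ("linear", "circular"):
            raise ConfigError(f"unknown-topology: {self.topology}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.rate_sd <= 0:
            raise ConfigError("rate_sd must be > 0")


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated dataset.

    Velocities are defined on the noise-free expression (U_clean,
    S_clean) evaluated at each cell's true time, so that
    ``Vu_true = alpha_true - beta * U_clean`` and
    ``Vs_true = beta * U_clean - gamma * S_clean`` hold exactly.
    """

    t_true: np.ndarray
    alpha_true: np.ndarray
    beta_true: np.ndarray
    gamma_true: np.ndarray
    Vu_true: np.ndarray
    Vs_true: np.ndarray
    U_clean: np.ndarray
    S_clean: np.ndarray


# ----------------------------------------------------------------------
# rate functions
# ----------------------------------------------------------------------

def _draw_rates(rng: np.random.Generator, p: int, rate_sd: float):
    beta = np.exp(rng.normal(0.0, rate_sd, size=p))
    gamma = np.exp(rng.normal(0.0, rate_sd, size=p))
    return beta, gamma


def _linear_alpha_params(rng: np.random.Generator, p: int):
    a = rng.uniform(1.0, 5.0, size=p)
    s = rng.uniform(0.1, 0.9, size=p)
    w = rng.uniform(0.02, 0.1, size=p)
    b = rng.uniform(0.0, 0.2, size=p)
    sign = np.ones(p)
    sign[rng.permutation(p)[: p // 2]] = -1.0  # mirrored (decreasing) half
    return a, s, w, b, sign


def _alpha_linear(t, a, s, w, b, sign):
    """Sigmoid-switch transcription rate; `t` scalar or (k,) array."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    return a * expit(sign * (t[:, None] - s) / w) + b


def _circular_alpha_params(rng: np.random.Generator, p: int):
    a = rng.uniform(1.0, 5.0, size=p)
    b = rng.uniform(0.0, 0.2, size=p)
    on = rng.uniform(0.0, 1.0, size=p)
    arc = rng.uniform(0.2, 0.8, size=p)
    return a, b, on, arc


def _alpha_circular(t, a, b, on, arc):
    """On/off-arc transcription rate on the unit circle."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    u = np.mod(t[:, None] - on, 1.0)
    return np.where(u < arc, a + b, b)


# ----------------------------------------------------------------------
# integration
# ----------------------------------------------------------------------

def _rk4_integrate(alpha_fn, beta, gamma, U0, S0, t_start, t_end,
                   step=_RK4_STEP):
    """4th-order Runge-Kutta on the splicing ODEs, all genes at once.

    Returns (tgrid, Ugrid, Sgrid) with Ugrid/Sgrid of shape (len(tgrid), p).
    """
    n_steps = int(round((t_end - t_start) / step))
    tgrid = t_start + step * np.arange(n_steps + 1)
    p = len(beta)
    Ug = np.empty((n_steps + 1, p))
    Sg = np.empty((n_steps + 1, p))
    U, S = np.asarray(U0, float).copy(), np.asarray(S0, float).copy()
    Ug[0], Sg[0] = U, S

    def deriv(t, U, S):
        a = alpha_fn(t)[0]
        return a - beta * U, beta * U - gamma * S

    for i in range(n_steps):
        t = tgrid[i]
        h = step
        k1u, k1s = deriv(t, U, S)
        k2u, k2s = deriv(t + h / 2, U + h / 2 * k1u, S + h / 2 * k1s)
        k3u, k3s = deriv(t + h / 2, U + h / 2 * k2u, S + h / 2 * k2s)
        k4u, k4s = deriv(t + h, U + h * k3u, S + h * k3s)
        U = U + h / 6 * (k1u + 2 * k2u + 2 * k3u + k4u)
        S = S + h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
        Ug[i + 1], Sg[i + 1] = U, S
    return tgrid, Ug, Sg


def _interp_rows(tgrid, grid, t_query):
    """Linear interpolation of (len(tgrid), p) grid values at t_query."""
    h = tgrid[1] - tgrid[0]
    pos = (np.asarray(t_query) - tgrid[0]) / h
    lo = np.clip(np.floor(pos).astype(int), 0, len(tgrid) - 2)
    frac = (pos - lo)[:, None]
    return (1.0 - frac) * grid[lo] + frac * grid[lo + 1]


def _apply_noise(M, noise_sd, rng):
    if noise_sd == 0:
        return M.copy()
    return np.maximum(M * (1.0 + noise_sd * rng.normal(size=M.shape)), 0.0)


def _stage_labels(t, n_stages=4):
    edges = np.quantile(t, np.linspace(0, 1, n_stages + 1)[1:-1])
    return [f"stage_{int(k)}" for k in np.searchsorted(edges, t)]


def _embedding_2pc(S_noisy):
    X = np.log1p(S_noisy)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, U.shape[1])
    emb = U[:, :k] * s[:k]
    if k < 2:
        emb = np.concatenate([emb, np.zeros((len(emb), 2 - k))], axis=1)
    return emb


# ----------------------------------------------------------------------
# simulators
# ----------------------------------------------------------------------

def simulate_linear(cfg: SimulationConfig) -> Tuple[OmicsDataset,
                                                    SimulationTruth]:
    """Linear-trajectory benchmark with sigmoid-switch transcription."""
    if cfg.topology != "linear":
        raise ConfigError("topology must be 'linear'")
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_cells, cfg.n_genes
    beta, gamma = _draw_rates(rng, p, cfg.rate_sd)
    a, s, w, b, sign = _linear_alpha_params(rng, p)
    t_true = rng.uniform(0.0, 1.0, size=n)

    def alpha_fn(t):
        return _alpha_linear(t, a, s, w, b, sign)

    alpha0 = alpha_fn(0.0)[0]
    U0 = alpha0 / beta
    S0 = beta * U0 / gamma
    tgrid, Ug, Sg = _rk4_integrate(alpha_fn, beta, gamma, U0, S0, 0.0, 1.0)
    U_clean = _interp_rows(tgrid, Ug, t_true)
    S_clean = _interp_rows(tgrid, Sg, t_true)
    alpha_true = alpha_fn(t_true)

    U_noisy = _apply_noise(U_clean, cfg.noise_sd, rng)
    S_noisy = _apply_noise(S_clean, cfg.noise_sd, rng)

    truth = SimulationTruth(
        t_true=t_true, alpha_true=alpha_true, beta_true=beta,
        gamma_true=gamma,
        Vu_true=alpha_true - beta * U_clean,
        Vs_true=beta * U_clean - gamma * S_clean,
        U_clean=U_clean, S_clean=S_clean,
    )
    ds = OmicsDataset(
        S=S_noisy, U=U_noisy,
        cell_ids=[f"cell_{i}" for i in range(n)],
        gene_ids=[f"gene_{g}" for g in range(p)],
        cell_labels=_stage_labels(t_true),
        embedding=_embedding_2pc(S_noisy),
    )
    return ds, truth


def circular_limit_cycle(cfg: SimulationConfig):
    """Noise-free limit-cycle grid for the circular simulator (diagnostics).

    Returns (tgrid in [0, 1], Ugrid, Sgrid) over one recorded period
    after burn-in.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_genes
    beta, gamma = _draw_rates(rng, p, cfg.rate_sd)
    a, b, on, arc = _circular_alpha_params(rng, p)

    def alpha_fn(t):
        return _alpha_circular(t, a, b, on, arc)

    alpha0 = alpha_fn(0.0)[0]
    U0 = alpha0 / beta
    S0 = beta * U0 / gamma
    tgrid, Ug, Sg = _rk4_integrate(alpha_fn, beta, gamma, U0, S0,
                                   0.0, float(_BURN_IN_PERIODS + 1))
    keep = tgrid >= _BURN_IN_PERIODS
    return tgrid[keep] - _BURN_IN_PERIODS, Ug[keep], Sg[keep]


def circular_params(cfg: SimulationConfig) -> dict:
    """Gene-level parameters a circular simulation would draw (diagnostics)."""
    rng = np.random.default_rng(cfg.seed)
    beta, gamma = _draw_rates(rng, cfg.n_genes, cfg.rate_sd)
    a, b, on, arc = _circular_alpha_params(rng, cfg.n_genes)
    t_true = rng.uniform(0.0, 1.0, size=cfg.n_cells)
    return {"beta": beta, "gamma": gamma, "a": a, "b": b, "on": on,
            "arc": arc, "t_true": t_true}


def _modality_profile(t, on, arc):
    """Smoothed indicator of the induction arc, opening 0.05 early."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    u = np.mod(t[:, None] - (on - _MODALITY_LEAD), 1.0)
    return expit(u / _MODALITY_EDGE) * expit((arc - u) / _MODALITY_EDGE)


def simulate_circular(cfg: SimulationConfig) -> Tuple[OmicsDataset,
                                                      SimulationTruth]:
    """Circular-trajectory benchmark: on/off-arc transcription switches.

    The ODEs are integrated over three full periods of burn-in so that
    sampled cells lie on the limit cycle; true times are interpreted
    modulo 1.
    """
    if cfg.topology != "circular":
        raise ConfigError("topology must be 'circular'")
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_cells, cfg.n_genes
    beta, gamma = _draw_rates(rng, p, cfg.rate_sd)
    a, b, on, arc = _circular_alpha_params(rng, p)
    t_true = rng.uniform(0.0, 1.0, size=n)

    def alpha_fn(t):
        return _alpha_circular(t, a, b, on, arc)

    alpha0 = alpha_fn(0.0)[0]
    U0 = alpha0 / beta
    S0 = beta * U0 / gamma
    tgrid, Ug, Sg = _rk4_integrate(alpha_fn, beta, gamma, U0, S0,
                                   0.0, float(_BURN_IN_PERIODS + 1))
    U_clean = _interp_rows(tgrid, Ug, t_true + _BURN_IN_PERIODS)
    S_clean = _interp_rows(tgrid, Sg, t_true + _BURN_IN_PERIODS)
    alpha_true = alpha_fn(t_true)

    U_noisy = _apply_noise(U_clean, cfg.noise_sd, rng)
    S_noisy = _apply_noise(S_clean, cfg.noise_sd, rng)

    O = None
    if cfg.with_modality:
        O_clean = _modality_profile(t_true, on, arc)
        O = np.maximum(O_clean + cfg.noise_sd * rng.normal(size=O_clean.shape),
                       0.0)

    truth = SimulationTruth(
        t_true=t_true, alpha_true=alpha_true, beta_true=beta,
        gamma_true=gamma,
        Vu_true=alpha_true - beta * U_clean,
        Vs_true=beta * U_clean - gamma * S_clean,
        U_clean=U_clean, S_clean=S_clean,
    )
    ds = OmicsDataset(
        S=S_noisy, U=U_noisy, O=O,
        cell_ids=[f"cell_{i}" for i in range(n)],
        gene_ids=[f"gene_{g}" for g in range(p)],
        cell_labels=_stage_labels(t_true),
        embedding=_embedding_2pc(S_noisy),
    )
    return ds, truth


def simulate_dataset(cfg: SimulationConfig):
    """Dispatch on `cfg.topology`."""
    if cfg.topology == "linear":
        return simulate_linear(cfg)
    return simulate_circular(cfg)


def modality_profile_noise_free(cfg: SimulationConfig) -> np.ndarray:
    """Pre-noise modality matrix of a circular simulation (diagnostics)."""
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_genes
    _draw_rates(rng, p, cfg.rate_sd)
    a, b, on, arc = _circular_alpha_params(rng, p)
    t_true = rng.uniform(0.0, 1.0, size=cfg.n_cells)
    return _modality_profile(t_true, on, arc)


# ----------------------------------------------------------------------
# perturbation protocols
# ----------------------------------------------------------------------

def _integerize(M: np.ndarray) -> np.ndarray:
    # round-half-to-even: deterministic and unbiased
    return np.rint(M).astype(np.int64)


def binomial_thinning(ds: OmicsDataset, keep_prob: float,
                      seed: int = 0) -> OmicsDataset:
    """Replace each (integerized) count x by a Binomial(x, keep_prob) draw."""
    if not (0.0 < keep_prob <= 1.0):
        raise ConfigError("keep_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    S = rng.binomial(_integerize(ds.S), keep_prob).astype(np.float64)
    U = rng.binomial(_integerize(ds.U), keep_prob).astype(np.float64)
    out = OmicsDataset(S=S, U=U, O=None if ds.O is None else ds.O.copy(),
                       cell_ids=list(ds.cell_ids), gene_ids=list(ds.gene_ids),
                       cell_labels=None if ds.cell_labels is None
                       else list(ds.cell_labels),
                       embedding=None if ds.embedding is None
                       else ds.embedding.copy())
    return out


def downsample_depth(ds: OmicsDataset, fraction: float,
                     seed: int = 0) -> OmicsDataset:
    """Resample each cell's total counts down to floor(fraction * total).

    Counts across S and U jointly are drawn without replacement
    (multivariate hypergeometric), preserving the composition.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    Si = _integerize(ds.S)
    Ui = _integerize(ds.U)
    p = ds.n_genes
    S_out = np.empty_like(Si)
    U_out = np.empty_like(Ui)
    for i in range(ds.n_cells):
        colors = np.concatenate([Si[i], Ui[i]])
        total = int(colors.sum())
        nsample = int(np.floor(fraction * total))
        draw = rng.multivariate_hypergeometric(colors, nsample)
        S_out[i] = draw[:p]
        U_out[i] = draw[p:]
    return OmicsDataset(S=S_out.astype(np.float64), U=U_out.astype(np.float64),
                        O=None if ds.O is None else ds.O.copy(),
                        cell_ids=list(ds.cell_ids), gene_ids=list(ds.gene_ids),
                        cell_labels=None if ds.cell_labels is None
                        else list(ds.cell_labels),
                        embedding=None if ds.embedding is None
                        else ds.embedding.copy())


def remove_cell_type(ds: OmicsDataset, label: str) -> OmicsDataset:
    """Drop all cells carrying `label` (disconnected-trajectory protocol)."""
    if ds.cell_labels is None:
        raise DataError("label-not-found: dataset has no cell labels")
    labels = np.asarray(ds.cell_labels)
    if label not in labels:
        raise DataError(f"label-not-found: {label}")
    keep = np.flatnonzero(labels != label)
    return ds.subset_cells(keep)
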