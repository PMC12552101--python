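"""Networks and forward computations of the joint pseudotime/velocity model.

Architecture (all widths configurable):

* a first fully connected layer shared by the state encoder and the
  time encoder maps the input X = (S, U[, O]) to a hidden
  representation;
* the state encoder head emits the posterior mean and log-variance of a
  d-dimensional latent state Z;
* the time encoder head emits a scalar squashed through a sigmoid to a
  pseudotime t in (0, 1);
* a drift network f_ode defines the latent ODE dZt/dt = f_ode(Zt),
  integrated by explicit Euler (or RK4) over the sorted cell times from
  the earliest cell's state Zt0;
* a single decoder f_d reconstructs X from both Z and Zt;
* a rate network f_alpha maps Zt to per-gene transcription rates, made
  nonnegative by a softplus by default.

Per-gene splicing and degradation rates beta, gamma are free parameters
kept positive through a log parameterization and initialized log-normal
(log-mean 0, log-sd 0.1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import MLP, Linear
from .errors import ConfigError, DataError

__all__ = [
    "ModelConfig",
    "ModelState",
    "LatentOutputs",
    "VelocityEstimate",
    "init_model",
    "encode",
    "integrate_latent",
    "decode",
    "transcription_rate",
    "compute_velocity",
]

_CHECKPOINT_SCHEMA = 1
_RATE_INIT_SD = 0.1  # log-sd of the log-normal beta/gamma initialization


@dataclass
class ModelConfig:
    latent_dim: int = 20
    hidden_dim: int = 128
    alpha_nonneg: bool = True
    ode_solver: str = "euler"
    activation: str = "elu"
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ConfigError("latent_dim must be >= 2")
        if self.hidden_dim < self.latent_dim:
            raise ConfigError("hidden_dim must be >= latent_dim")
        if self.ode_solver not in ("euler", "rk4"):
            raise ConfigError(f"unknown-solver: {self.ode_solver}")


@dataclass
class LatentOutputs:
    """Per-cell latent quantities from one forward pass."""

    mu: Tensor
    log_sigma2: Tensor
    Z: Tensor
    t: Tensor                       # (n,), strictly inside (0, 1)
    t_raw: Tensor                   # pre-sigmoid time output
    order: np.ndarray               # permutation sorting t ascending
    Zt0: Optional[Tensor] = None    # initial latent state (1, d)
    Zt: Optional[Tensor] = None     # ODE-evolved states, original cell order


@dataclass
class VelocityEstimate:
    """Cell x gene transcription rates and velocities.

    Fields hold numpy arrays in public use; internally the same
    container may carry autodiff tensors during training.
    """

    alpha: object
    Vu: object
    Vs: object


class ModelState:
    """All trainable parameters of the model."""

    def __init__(self, cfg: ModelConfig, n_genes: int, n_features_total: int,
                 reverse_time: bool = False):
        if n_genes < 1 or n_features_total < 2 * n_genes:
            raise ConfigError("inconsistent feature dimensions")
        self.cfg = cfg
        self.n_genes = n_genes
        self.n_features = n_features_total
        d, hid = cfg.latent_dim, cfg.hidden_dim
        rng = np.random.default_rng(cfg.seed)

        self.enc_shared = Linear(n_features_total, hid, rng)  # shared layer
        self.enc_mu = Linear(hid, d, rng)
        self.enc_logvar = Linear(hid, d, rng)
        self.ft_head = Linear(hid, 1, rng)
        self.fode = MLP(d, hid, d, rng, cfg.activation)
        self.fd = MLP(d, hid, n_features_total, rng, cfg.activation)
        self.falpha = MLP(d, hid, n_genes, rng, cfg.activation)
        self.log_beta = Tensor(rng.normal(0.0, _RATE_INIT_SD, size=n_genes),
                               requires_grad=True)
        self.log_gamma = Tensor(rng.normal(0.0, _RATE_INIT_SD, size=n_genes),
                                requires_grad=True)
        if reverse_time:
            # negate the pre-sigmoid time output: t -> 1 - t at initialization
            self.ft_head.W.data *= -1.0
            self.ft_head.b.data *= -1.0
        self._act = {"elu": lambda t: t.elu(), "tanh": lambda t: t.tanh(),
                     "softplus": lambda t: t.softplus()}[cfg.activation]

    # ------------------------------------------------------------------
    @property
    def beta(self) -> np.ndarray:
        return np.exp(self.log_beta.data)

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.log_gamma.data)

    def parameters(self):
        return (self.enc_shared.parameters() + self.enc_mu.parameters()
                + self.enc_logvar.parameters() + self.ft_head.parameters()
                + self.fode.parameters() + self.fd.parameters()
                + self.falpha.parameters() + [self.log_beta, self.log_gamma])

    # ------------------------------------------------------------ checkpoint
    def save(self, path: str):
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        meta = {"schema": _CHECKPOINT_SCHEMA, "config": asdict(self.cfg),
                "n_genes": self.n_genes, "n_features": self.n_features}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "ModelState":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            if meta.get("schema") != _CHECKPOINT_SCHEMA:
                raise DataError("checkpoint-schema-mismatch")
            state = cls(ModelConfig(**meta["config"]), meta["n_genes"],
                        meta["n_features"])
            for i, p in enumerate(state.parameters()):
                p.data = np.asarray(f[f"param_{i}"], dtype=np.float64)
        return state


def init_model(cfg: ModelConfig, n_genes: int, n_features_total: int,
               reverse_time: bool = False) -> ModelState:
    """Initialize all parameters; deterministic under `cfg.seed`."""
    return ModelState(cfg, n_genes, n_features_total, reverse_time)


# ----------------------------------------------------------------------
# forward ops
# ----------------------------------------------------------------------

def encode(state: ModelState, X, sample: bool = False,
           rng: Optional[np.random.Generator] = None) -> LatentOutputs:
    """Posterior parameters, latent sample and pseudotime for a batch.

    With `sample` on, Z = mu + sigma * E with E ~ N(0, I) drawn from
    `rng`; with `sample` off, Z = mu (evaluation mode).
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    if X.shape[1] != state.n_features:
        raise DataError(
            f"shape-mismatch: expected {state.n_features} features, "
            f"got {X.shape[1]}")
    h = state._act(state.enc_shared(X))
    mu = state.enc_mu(h)
    log_sigma2 = state.enc_logvar(h)
    if sample:
        if rng is None:
            raise ConfigError("sampling requires an rng")
        E = rng.standard_normal(mu.shape)
        Z = mu + (log_sigma2 * 0.5).exp() * E
    else:
        Z = mu
    t_raw = state.ft_head(h).reshape(-1)
    t = t_raw.sigmoid()
    order = np.argsort(t.data, kind="stable")
    return LatentOutputs(mu=mu, log_sigma2=log_sigma2, Z=Z, t=t, t_raw=t_raw,
                         order=order)


def integrate_latent(state: ModelState, Zt0: Tensor, times) -> Tensor:
    """Integrate dZt/dt = f_ode(Zt) along sorted `times` from Zt0.

    `times` may be a Tensor (gradients flow into the time increments) or
    an array.  Output row k is the state at times[k]; row 0 is Zt0.
    """
    times_t = times if isinstance(times, Tensor) else Tensor(times)
    tvals = times_t.data
    if np.any(np.diff(tvals) < 0):
        raise DataError("times-not-sorted")
    n = len(tvals)
    z = Zt0.reshape(1, -1)
    if n == 1:
        return z
    idx = np.arange(n)
    dts = times_t.take(idx[1:]) - times_t.take(idx[:-1])  # (n-1,)
    rows = [z]
    rk4 = state.cfg.ode_solver == "rk4"
    for k in range(n - 1):
        dt = dts.take([k])  # (1,)
        if rk4:
            k1 = state.fode(z)
            k2 = state.fode(z + k1 * (dt * 0.5))
            k3 = state.fode(z + k2 * (dt * 0.5))
            k4 = state.fode(z + k3 * dt)
            z = z + (k1 + k2 * 2.0 + k3 * 2.0 + k4) * (dt * (1.0 / 6.0))
        else:
            z = z + state.fode(z) * dt
        rows.append(z)
    return concat(rows, axis=0)


def decode(state: ModelState, Z: Tensor) -> Tensor:
    """Reconstruct X from any latent matrix; one decoder for both paths."""
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    if Z.shape[-1] != state.cfg.latent_dim:
        raise DataError("shape-mismatch: latent dimension")
    return state.fd(Z)


def transcription_rate(state: ModelState, Zt: Tensor) -> Tensor:
    """Cell-specific transcription rates alpha = g(f_alpha(Zt)).

    g is softplus when `alpha_nonneg` is on (default), identity
    otherwise.
    """
    Zt = Zt if isinstance(Zt, Tensor) else Tensor(Zt)
    if Zt.shape[-1] != state.cfg.latent_dim:
        raise DataError("shape-mismatch: latent dimension")
    raw = state.falpha(Zt)
    return raw.softplus() if state.cfg.alpha_nonneg else raw


def compute_velocity(U, S, alpha, beta, gamma) -> VelocityEstimate:
    """Kinetic velocities Vu = alpha - beta*U and Vs = beta*U - gamma*S.

    beta and gamma broadcast gene-wise; inputs may be numpy arrays or
    autodiff tensors (mixing is allowed).
    """
    beta_arr = beta.data if isinstance(beta, Tensor) else np.asarray(beta)
    gamma_arr = gamma.data if isinstance(gamma, Tensor) else np.asarray(gamma)
    if np.any(beta_arr <= 0) or np.any(gamma_arr <= 0):
        raise DataError("invalid-rates: beta and gamma must be positive")
    bU = beta * U
    Vu = alpha - bU
    Vs = bU - gamma * S
    return VelocityEstimate(alpha=alpha, Vu=Vu, Vs=Vs)
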