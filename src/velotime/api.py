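"""Model/Results front-end over the training machinery.

`VelocityPseudotimeModel` is constructed from an :class:`OmicsDataset`
(or an AnnData with spliced/unspliced layers); `fit()` returns a
`VelocityResults` carrying the pseudotime, velocities, kinetic rates,
diagnostics and a `summary()` table, with `predict()` available for
held-out cells.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .data_io import OmicsDataset, PreprocessConfig, preprocess
from .model import ModelConfig, ModelState
from .objective import LossWeights
from .reconstruct import EulerConfig
from .train import FitResult, TrainConfig, fit as _fit, predict as _predict

__all__ = ["VelocityPseudotimeModel", "VelocityResults"]


class VelocityPseudotimeModel:
    """Joint pseudotime / RNA-velocity model for one dataset.

    Parameters
    ----------
    dataset
        An :class:`OmicsDataset`.  Set `do_preprocess` to run the
        standard pipeline (normalization, variable genes, KNN moment
        smoothing) first; leave it off if the data are already
        smoothed moments.
    """

    def __init__(self, dataset: OmicsDataset,
                 model_config: Optional[ModelConfig] = None,
                 loss_weights: Optional[LossWeights] = None,
                 euler_config: Optional[EulerConfig] = None,
                 do_preprocess: bool = False,
                 preprocess_config: Optional[PreprocessConfig] = None):
        if do_preprocess:
            dataset = preprocess(dataset, preprocess_config)
        self.dataset = dataset
        self.model_config = model_config or ModelConfig()
        self.loss_weights = loss_weights or LossWeights()
        self.euler_config = euler_config or EulerConfig()

    @classmethod
    def from_anndata(cls, adata, **kwargs) -> "VelocityPseudotimeModel":
        return cls(OmicsDataset.from_anndata(adata), **kwargs)

    def fit(self, train_config: Optional[TrainConfig] = None,
            **train_kwargs) -> "VelocityResults":
        tcfg = train_config or TrainConfig(**train_kwargs)
        res = _fit(self.dataset, self.model_config, self.loss_weights,
                   tcfg, self.euler_config)
        return VelocityResults(self, res, tcfg)


class VelocityResults:
    """Estimates and diagnostics from a completed fit."""

    def __init__(self, model: VelocityPseudotimeModel, result: FitResult,
                 train_config: TrainConfig):
        self.model = model
        self.result = result
        self.train_config = train_config

    # ------------------------------------------------------------ estimates
    @property
    def pseudotime(self) -> np.ndarray:
        return self.result.t

    @property
    def velocity(self) -> np.ndarray:
        """Spliced RNA velocity dS/dt (cells x genes)."""
        return np.asarray(self.result.velocity.Vs)

    @property
    def unspliced_velocity(self) -> np.ndarray:
        return np.asarray(self.result.velocity.Vu)

    @property
    def transcription_rate(self) -> np.ndarray:
        return np.asarray(self.result.velocity.alpha)

    @property
    def splicing_rate(self) -> np.ndarray:
        return self.result.model.beta

    @property
    def degradation_rate(self) -> np.ndarray:
        return self.result.model.gamma

    @property
    def latent_states(self) -> np.ndarray:
        return self.result.Zt

    @property
    def state(self) -> ModelState:
        return self.result.model

    # ---------------------------------------------------------------- misc
    def predict(self, dataset: OmicsDataset):
        """Pseudotime/velocity for (possibly unseen) cells."""
        return _predict(self.result.model, dataset)

    def save_checkpoint(self, path: str):
        self.result.model.save(path)

    def loss_dataframe(self):
        import pandas as pd

        return pd.DataFrame([vars(b) for b in self.result.loss_history])

    def to_anndata(self):
        adata = self.model.dataset.to_anndata()
        adata.obs["pseudotime"] = self.pseudotime
        adata.layers["velocity"] = self.velocity
        adata.layers["velocity_u"] = self.unspliced_velocity
        adata.layers["transcription_rate"] = self.transcription_rate
        adata.var["beta"] = self.splicing_rate
        adata.var["gamma"] = self.degradation_rate
        return adata

    def summary(self) -> str:
        ds = self.model.dataset
        res = self.result
        last = res.loss_history[-1] if res.loss_history else None
        lines = [
            "Joint pseudotime / RNA-velocity fit",
            "=" * 52,
            f"{'cells':<28}{ds.n_cells}",
            f"{'genes':<28}{ds.n_genes}",
            f"{'input features (m)':<28}{ds.n_features}",
            f"{'latent dimension':<28}{self.model.model_config.latent_dim}",
            f"{'epochs run':<28}{len(res.loss_history)}",
            f"{'direction flipped':<28}{res.flipped}",
            f"{'retrained (reversed init)':<28}{res.retrained}",
            f"{'Pearson direction score':<28}{res.l_pearson:+.4f}",
            f"{'velocity-pseudotime corr':<28}{res.vpt_corr:+.4f}",
            f"{'pseudotime range':<28}"
            f"[{res.t.min():.4f}, {res.t.max():.4f}]",
        ]
        if last is not None:
            lines += [
                "-" * 52,
                "final loss breakdown (per cell)",
                f"{'  Lt1 (reconstruction)':<28}{last.lt1:.4f}",
                f"{'  Lt2 (-KL)':<28}{last.lt2:.4f}",
                f"{'  Lt3 (Z/Zt consistency)':<28}{last.lt3:.4f}",
                f"{'  Lv1 (Euler recon.)':<28}{last.lv1:.4f}",
                f"{'  Lv2 (unspliced penalty)':<28}{last.lv2:.4f}",
                f"{'  total':<28}{last.total:.4f}",
            ]
        lines.append("=" * 52)
        return "\n".join(lines)
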