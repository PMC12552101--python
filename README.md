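# velotime

Joint inference of a **global cellular pseudotime** and **cell-specific RNA
velocity** from spliced/unspliced single-cell expression, optionally
integrating a second omic modality (e.g. chromatin accessibility) measured on
the same cells.

## The problem

Single-cell RNA-seq is a snapshot: it shows where each cell is, not where it
is going. RNA velocity recovers short-term direction from the splicing
kinetics of each gene,

```
dU_ig/dt = α_ig − β_g U_ig          (transcription, splicing)
dS_ig/dt = β_g U_ig − γ_g S_ig      (splicing, degradation)
```

where `U`/`S` are unspliced/spliced abundances, `β_g`, `γ_g` are per-gene
splicing and degradation rates, and the RNA velocity of cell *i* is
`V_i^s = dS_i/dt`. Classical velocity models assume a constant transcription
rate `α` and fit each gene on its own clock, which biases both the rates and
any pseudotime later assembled from them.

`velotime` instead couples the two estimates so they reinforce each other:

* A variational autoencoder encodes each cell's profile `X = (S, U[, O])`
  into a latent state `Z ~ N(μ, σ²I)` and, through a time encoder sharing its
  first layer, into a scalar pseudotime `t = σ(f_t(X)) ∈ (0, 1)` — one global
  clock for all genes.
* A neural ODE `dZ_t/dt = f_ode(Z_t)` evolves the earliest cell's state along
  the sorted pseudotimes, giving a second, dynamics-consistent latent path
  `Z_t`; one decoder reconstructs `X` from both `Z` and `Z_t`.
* The transcription rate is **state-dependent**: `α = f_α(Z_t)`, so it can
  vary along development; `β_g`, `γ_g` stay constant per gene
  (log-parameterized, log-normal initialized).
* Expression is reconstructed along pseudotime by explicit Euler steps
  `X̂_{t_{k}} = X̂_{t_{k-1}} + V̂(t_{k-1})·(t_k − t_{k-1})` with a reset to the
  observed values every `l = 50` cells, so the squared reconstruction error
  (`Lv1`) scores velocity and pseudotime jointly. A penalty (`Lv2`) drives the
  unspliced velocity to zero on entries above the 95th expression percentile,
  where kinetics should be near saturation.
* The total objective `L = (Lt1 + Lt2 + Lt3) + λ_v (Lv1 + Lv2)` combines the
  two reconstruction paths, the KL term and a `Z`/`Z_t` consistency term;
  training maximizes it with Adam/AMSGrad mini-batches.
* Because the ODE solution is invariant to reversing both time and velocity,
  a post-hoc Pearson score `λ_u corr(V̂^s, U) − λ_s corr(V̂^s, S)` fixes the
  direction (flipping `t → 1 − t`, `V → −V` when negative), and a
  velocity-derived pseudotime consistency check can trigger one retrain from
  a time-reversed initialization.

A fully kinetics-aware simulator (linear and circular topologies, optional
accessibility-like modality, binomial thinning / depth down-sampling /
cell-type removal perturbations) and the benchmark metrics (pseudotime
Pearson and circular cross-correlation, per-cell velocity correlation,
stability cosine, CBDir/CBDir2/TransCosine/LenAcc boundary metrics) are
included, so every claim the package makes can be scored against ground
truth.

## Worked example

```python
import numpy as np
import velotime as vt
from velotime.api import VelocityPseudotimeModel
from scipy.stats import spearmanr

cfg = vt.SimulationConfig(n_cells=500, n_genes=100, noise_sd=0.1, seed=0)
ds, truth = vt.simulate_linear(cfg)

model = VelocityPseudotimeModel(ds, model_config=vt.ModelConfig(seed=0),
                                do_preprocess=True)
res = model.fit(vt.TrainConfig(epochs=400, seed=0))
print(res.summary())
print("Pearson(t, t_true)   = %.3f" % np.corrcoef(res.pseudotime, truth.t_true)[0, 1])
print("velocity correlation = %.3f" % vt.velocity_correlation(res.velocity, truth.Vs_true))
```

prints

```
Joint pseudotime / RNA-velocity fit
====================================================
cells                       500
genes                       100
input features (m)          200
latent dimension            20
epochs run                  188
direction flipped           False
retrained (reversed init)   False
Pearson direction score     +0.0580
velocity-pseudotime corr    +0.8796
pseudotime range            [0.1830, 0.8201]
----------------------------------------------------
final loss breakdown (per cell)
  Lt1 (reconstruction)      -4.5806
  Lt2 (-KL)                 -17.9476
  Lt3 (Z/Zt consistency)    -4.7840
  Lv1 (Euler recon.)        -1.3124
  Lv2 (unspliced penalty)   -0.0827
  total                     -28.7073
====================================================
Pearson(t, t_true)   = 0.924
velocity correlation = 0.605
```

The fitted pseudotime orders cells along the true developmental axis
(Pearson 0.92 against the hidden simulation time), the per-cell velocity
profiles correlate 0.61 with the true kinetic velocities, the positive
direction score means no flip was needed, and the velocity-pseudotime
consistency of +0.88 confirms pseudotime and velocity field agree. Early
stopping ended training at epoch 188 of the 400 allowed.

The same pipeline is scriptable from a shell:

```bash
velotime simulate --topology linear --n-cells 500 --n-genes 100 --seed 0 --out sim/
velotime train --input sim/sim.h5ad --epochs 400 --seed 0 --out fit/
velotime evaluate --input sim/sim.h5ad --truth sim/ --fit fit/ --out report.json
```

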