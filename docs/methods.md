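# Methods

## Model

Each cell contributes a feature vector `X = (S, U)` of spliced and unspliced
expression over `p` genes (`m = 2p` features), extended to `X = (S, U, O)`
(`m = 2p + h`) when a second modality with `h` features is present. The model
has five networks and two free kinetic parameter vectors:

* **shared encoder layer** `m → hidden` (width 128 by default), feeding
* **state encoder head** `hidden → (μ, log σ²)`, each of latent dimension
  `d = 20`, defining the posterior `q(Z|X) = N(μ, σ² I)` with reparameterized
  samples `Z = μ + σ ⊙ E`;
* **time encoder head** `hidden → 1`, squashed by a sigmoid to a pseudotime
  `t ∈ (0, 1)`; sharing the first layer ties the time estimate to the same
  representation the state encoder uses;
* **drift network** `f_ode: d → d` (two layers), defining the latent ODE
  `dZ_t/dt = f_ode(Z_t)`. Cells are sorted by `t`; the earliest cell's state
  is the initial value `Z_{t_0}` (its posterior mean in evaluation, its
  sampled `Z` during training so gradients flow), and explicit Euler steps
  over the successive pseudotime increments produce `Z_{t_k}` for every cell
  (RK4 is available as a config option);
* **decoder** `f_d: d → m`, applied to *both* `Z` and `Z_t` — one decoder, so
  the two latent paths must agree about what the data look like;
* **rate network** `f_α: d → p`, mapping the evolved state to per-cell
  transcription rates; a softplus keeps `α ≥ 0` (an identity output is
  available for a strictly linear readout);
* **kinetic rates** `β, γ > 0` per gene, parameterized on the log scale and
  initialized log-normal with log-mean 0 and log-sd 0.1.

Velocities follow from the splicing ODEs at any expression values:
`V^u = α − β ⊙ U`, `V^s = β ⊙ U − γ ⊙ S`. Reported velocities are evaluated
at the KNN-smoothed observed expression — the same layer the losses see.

## Objective

All terms are negated squared errors (or a negated KL), summed over features
and averaged per cell, so the objective does not scale with batch size:

* `Lt1 = −ω‖X − X̂^n‖² − (1−ω)‖X − X̂^t‖²` — reconstruction from `Z` and from
  `Z_t`; `ω = 0.5`.
* `Lt2 = −KL(q(Z|X) ‖ N(0, I))`, in closed form.
* `Lt3 = −‖Z − Z_t‖²` — the sampled and ODE-evolved states must agree.
* `Lv1 = −‖X_su − X̂_su‖²` — segmented Euler reconstruction error: within
  each run of `l = 50` consecutive cells (in pseudotime order) the first
  cell's reconstruction is pinned to its observation and each next cell is
  predicted by one Euler step using the velocity at the *running* estimate,
  with `α` taken at the previous cell's `Z_t`. The reset interval bounds the
  accumulated first-order error; the time increments `t_k − t_{k−1}` are part
  of the computation graph, which is how pseudotime learns from kinetics.
* `Lv2 = −Σ_{(i,g)∈Ω} (V^u_{ig})²` where `Ω` collects entries whose total
  expression `S+U` strictly exceeds the per-gene 95th percentile
  (per mini-batch). Near-saturated entries should be kinetically stable;
  penalizing `V^u` there keeps `α` from absorbing arbitrary structure. The
  gate can alternatively be computed on `S` or `U` alone or from global
  percentiles.

Total: `L = Lt1 + Lt2 + Lt3 + λ_v (Lv1 + Lv2)` with `λ_v = 1`; the optimizer
minimizes `−L`.

## Optimization

Adam with learning rate 0.01, weight decay 0.01, epsilon 0.01 and AMSGrad;
mini-batches of up to 1024 cells (shuffled each epoch, seeded); 400 epochs by
default with early stopping on the best observed total loss (patience 30
epochs). The per-epoch loss is noisy under posterior sampling, so early
stopping measures "no new best" rather than strict decrease; on the 500-cell
benchmark it typically stops near epoch 190. Everything — initialization,
shuffling, posterior sampling — derives from explicit seeds, and all
arithmetic is float64 on a single thread, so repeated runs are bit-identical.

Networks and optimizer run on a small reverse-mode automatic-differentiation
core written on numpy (`velotime/_autodiff.py`): a recorded-tape design with
exactly the operator set the model needs. The sequential parts of the graph
(the latent ODE chain and the Euler recursion) dominate the tape; the Euler
recursion is vectorized across segments so its depth is the segment length,
not the cell count.

## Direction handling

The ODE fit is invariant to reversing pseudotime and velocity together, so
orientation must be fixed post hoc. Because `V^s = βU − γS`, a correctly
oriented spliced velocity correlates positively with `U` and negatively with
`S`; the score `λ_u corr(V̂^s_i, U_i) − λ_s corr(V̂^s_i, S_i)` (per-cell
correlations across genes, averaged; `λ_u = λ_s = 0.5`; a global-correlation
mode exists) decides a flip. Flips negate the *pre-sigmoid* time output
(`1 − σ(x) = σ(−x)`) and the velocities, making the flip an exact involution
at the bit level.

A second check guards against a badly oriented initialization: a velocity
pseudotime is computed by softmax-normalized cosine transition scores between
each cell's velocity and the displacement to its KNN neighbors, iterating the
transition operator from a uniform distribution (tolerance 1e-8, at most
1000 iterations; largest component if the graph is disconnected) and
rank-normalizing the result. If it correlates negatively with the fitted `t`,
the model is retrained once from a time-reversed initialization (the time
head's weights negated at epoch 0). Only the sign of this correlation is
used, so any order-preserving variant of the score would do.

## Preprocessing

Per-cell size-factor normalization of each layer to its median total;
selection of the most variable genes by spliced dispersion (variance/mean,
2000 by default); first-order moment smoothing of `S` and `U` — the mean over
each cell's `k = 30` nearest neighbors (self included, Euclidean metric, ties
broken by index) on 30 principal components of the normalized log1p spliced
matrix; the modality is normalized and log1p-transformed. The unspliced
layer is smoothed with the spliced-built graph, not a joint graph. The PCA
uses a full (deterministic) SVD; no step involves randomness. Each step can
be disabled.

## Simulator

The simulator generates data from the same family of kinetics the model
assumes — constant per-gene `β, γ ~ LogNormal(0, 0.1)` and a time-varying
transcription rate — which is precisely what makes it a *calibration*
benchmark: it tests whether the estimation machinery recovers known
parameters, not whether the model family fits real data.

* **Linear topology**: cell times `t_i ~ U(0,1)`;
  `α_g(t) = a_g σ((t−s_g)/w_g) + b_g` with amplitude `a_g ~ U(1,5)`, switch
  time `s_g ~ U(0.1,0.9)`, width `w_g ~ U(0.02,0.1)`, basal level
  `b_g ~ U(0,0.2)`, and a random half of the genes mirrored (decreasing).
  The ODEs are integrated by RK4 at step 1e-3 from the steady state of
  `α(0)`, and evaluated at each cell's time.
* **Circular topology**: each gene is induced (`α = a_g + b_g`) on an arc of
  the unit circle (start uniform, length `U(0.2, 0.8)`) and basal elsewhere;
  integration runs through 8 burn-in periods before the recorded one, which
  closes the limit cycle to < 2 % (degradation rates as slow as e^−0.2 per
  period make 3 periods insufficient). The optional modality gives each gene
  one accessibility-like feature: a smoothed indicator (logistic edges,
  width 0.02) of the induction arc shifted 0.05 earlier — accessibility
  opening before transcription.
* **Noise**: multiplicative Gaussian, `x → x(1 + 0.1·N(0,1))` clipped at 0,
  applied after the ODE solve so stored truth rates and velocities (defined
  on the noise-free expression) remain exact.
* **Perturbations**: binomial thinning (each integerized count
  `x → Binomial(x, keep_prob)`; integerization is round-half-to-even),
  depth down-sampling (each cell's pooled S+U counts resampled without
  replacement to `floor(fraction × total)`, i.e. multivariate
  hypergeometric), and removal of a labeled cell population.

What the simulator does **not** emulate: UMI count statistics and dropout,
doublets, batch effects, multiple branching lineages, and genes that violate
the constant-`β,γ` assumption. Passing the benchmark therefore shows the
estimator is correct and stable under the model's own assumptions plus
moderate noise — not that those assumptions hold in any particular tissue.

## Numerical choices

* Activation: ELU throughout (a smooth rectifier keeps the ODE drift and the
  gradients through long Euler chains well behaved; tanh trains markedly
  worse here and ReLU is not C¹).
* Negative running estimates inside the Euler recursion are *not* clipped, so
  the reconstruction loss can penalize them.
* Segmentation uses a stable sort (ties by original index); a leftover
  singleton segment is merged into its predecessor so every segment has at
  least two cells.
* Percentiles use linear interpolation; the `Ω` gate is a strict inequality,
  so constant genes contribute nothing.
* Trailing mini-batches smaller than 4 cells are merged into the previous
  batch.
* A divergent (non-finite) loss aborts training with the epoch index.
* Checkpoints are a single `.npz` with all parameter tensors plus the model
  configuration under a schema tag.

## Problem sizes

The reference benchmark is 500 cells × 100 genes at 10 % noise; a full
400-epoch fit takes well under a minute on one CPU, and the reproduction
script (two full fits plus diagnostics) a couple of minutes. The multi-seed
direction sweep in the test suite uses 150-epoch fits, which are already
direction-stable.

## Known limitations

* **Per-gene rate identifiability.** With the rate network free to absorb
  per-gene scale into `α`, the splicing rate `β` is constrained only through
  the spliced channel of the Euler reconstruction. Under 10 % multiplicative
  noise and KNN smoothing, and with the true rates spread only ~10 % around
  1, the per-gene `γ/β` ordering is recovered weakly (Spearman ≈ 0.3–0.6
  depending on epochs and seed); a windowed-integral regression oracle given
  the *true* time reaches only ≈ 0.7 on the same data, so most of the gap is
  an information limit of these conditions rather than an optimization
  failure. Absolute rates are additionally confounded with the global time
  scaling of `t ∈ (0,1)`. Velocity direction and per-cell velocity profiles,
  which pool over genes, are much better determined.
* **Count-depth sensitivity of perturbation protocols.** Thinning operates on
  integerized counts; on the simulator's continuous scale (entries ~0–6)
  integerization alone is a substantial perturbation, so stability cosines
  under 50 % thinning (~0.5 median) are far below what the same protocol
  yields on deeply sequenced real data. The same-data, different-seed
  reproducibility cosine is ≈ 0.84.
* Early stopping on the noisy sampled objective can trigger prematurely on
  small datasets (a few hundred cells); raising `early_stop_patience` or
  `epochs` is the remedy.
* The model assumes one continuous trajectory; purely cyclic data are handled
  only insofar as the fixed `β, γ` keep velocities sensible, and strongly
  disconnected populations can distort the global clock.
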