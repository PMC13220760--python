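# Methods

## Model

`steer` infers RNA velocity under the two-equation splicing model

    dU_g/dt = α_g(C(z), t) − β_g(C(z), t)·U_g
    dS_g/dt = β_g(C(z), t)·U_g − γ_g(C(z), t)·S_g

where U_g and S_g are the unspliced and spliced abundances of gene g,
t is a per-cell latent (kinetic) time, and C(z) ∈ {1…K} is a discrete
kinetic-regime assignment driven by the latent state.  The structure of
the kinetic law matters: the latent state acts on the rates *only
through the regime assignment*.  Each regime (expert) is therefore a
family of per-gene rate curves over time, t → (α_g, β_g, γ_g), and all
cell-to-cell rate variation beyond time comes from which regime a cell
belongs to.  A soft gating network maps the cell representation [z‖t]
to a distribution over regimes; reported outputs use hard (argmax)
routing.  Velocities are the model identities v_u = α − βU and
v_s = βU − γS evaluated on smoothed, size-normalized counts.

An optional variant (`expert_inputs="zt"`) conditions the experts on
the full latent state.  It is deliberately not the default: a single
latent-conditioned expert is already a cell-specific model, which makes
the K = 1 "no mixture" reference fit almost as well as the full model
and empties the regime decomposition of meaning.

### Identifiability and gauges

Latent time has no physical unit: rescaling t → c·t while dividing all
rates by c leaves every trajectory invariant, and any monotone
reparameterization of t can be absorbed by time-dependent rates.  Two
consequences shape the implementation:

* **Rate recovery is assessed on scale-free quantities**, primarily the
  per-gene ratio γ/β (pinned near steady state by U/S), or rates after
  matching the median β to a reference.
* **The time gauge is fixed by rank-uniformization**: before kinetic
  fitting, t is mapped to uniform ranks on [0, 1].  The ordering — the
  only thing the temporal losses define — is untouched (all rank
  statistics are invariant), but the sigmoid's end-compression is
  removed.  Without this, constant-rate fits along the warped axis are
  biased and the rate curves become ill-conditioned.  `time_gauge="raw"`
  disables it.

## Architecture

* **Unified cell graph.**  kNN by Euclidean distance on the top 30
  principal components of log1p size-normalized spliced counts (k = 30
  for dissociated data; k = 15 plus a k = 8 spatial-proximity kNN when
  tissue coordinates are present), symmetrized by union, binary edges
  with per-edge origin flags.
* **Graph-attention autoencoder (GAAE).**  Two attention layers (hidden
  128, bottleneck d_z = 32, 2 heads in layer 1 averaged into a single
  per-edge attention vector).  Layer 2 and the one-layer decoder
  *reuse* layer-1 attention — exactly one attention matrix exists per
  model — which preserves first-order neighborhood structure and limits
  over-smoothing.  Self-loops are always present, so isolated cells
  attend to themselves.  Reconstruction target is log1p(U)‖log1p(S);
  loss is mean squared error.  The sizes are modest on purpose: the
  attention backward pass is memory-bound and scales with width×heads,
  and these sizes train full-graph on one CPU in minutes while
  reconstructing the simulations as well as wider nets.
* **Kinetic-time encoder.**  z → t through a small feed-forward net and
  a logistic squashing; reported times are min–max normalized.
* **Gating and experts.**  Gating: feed-forward net on [z‖t], row-wise
  softmax at temperature τ = 1, K = 8 by default.  Each expert: an
  independent feed-forward net (hidden 64) from t to 3·g
  softplus-positive outputs.  Two numerical devices make the experts
  trainable: a data-derived output gain (1 / median forward time step —
  rates per unit latent time are large on a compressed axis), and
  initialization of the output layer at the global per-gene
  constant-rate least-squares fit (closed form; output weights zeroed
  so training starts exactly there).  Every expert starts at this
  single-regime fit and the routing machinery differentiates them.

## Losses and training

Three gradient stages plus a refinement, all full-batch Adam (lr 1e−3):

1. **Embedding.**  GAAE reconstruction on highly variable genes
   (dispersion ranking, ties by gene index).  The embedding is
   clustered (Leiden, resolution 1.0, on a z-kNN graph) into coarse
   groups used for gene filtering and tendency estimation.
2. **Temporal refinement** (300 epochs — the time ordering is the
   backbone of everything downstream).  The encoder is re-trained on
   the informative gene set together with the time encoder under
   * smoothness: Σ_edges (t_i − t_j)² / |E|;
   * directionality: mean over directed edges of
     softplus(−c·(t_j − t_i)·d_ij), where d_ij = ⟨S_j − S_i, delta_i⟩
     projects the neighbor displacement onto the transcriptional
     tendency delta = U − k_g·S (k_g fit through the origin on the
     extreme 5% S-quantiles per coarse group), normalized by its mean
     magnitude and sharpened with c = 5.  Weights λ_smooth = 0.1,
     λ_dir = 1: the stronger directionality weight pins the ordering
     (Spearman ≈ 0.98 on the bifurcating simulation versus ≈ 0.7 at a
     0.1 weight).  The losses fix t up to reflection; if the mean sign
     agreement with the tendency is negative, t is flipped.
3. **Kinetics** (250 epochs).  The embedding and time are frozen (they
   are converged; letting reconstruction keep drifting z while the
   time encoder lags measurably erodes the ordering; end-to-end
   fine-tuning remains available via `stage3_finetune_embedding`).
   Gating and experts train under λ_dyn·L_dyn + λ_cut·L_mincut
   (λ_dyn = 1, λ_cut = 0.5) with soft mixing, the forward-difference
   dynamical loss over graph pairs with 0 < t_j − t_i ≤ 0.2 (capped at
   20 000 pairs per epoch by seeded subsample), and t detached inside
   the residual.
4. **Hard-EM refinement.**  E-step: each cell's mean residual under
   each expert's kinetics, smoothed twice over the graph (the EM
   counterpart of MinCUT's topological consistency), argmin
   assignment.  M-step: each expert refit on its own cells' forward
   pairs (40–60 epochs at lr 3e−4 — small steps, because the experts
   start near their optimum and larger steps wander away from it).
   Up to 6 iterations or until < 1% of labels change; finally the gate
   is distilled to the refined assignment by cross-entropy so the
   reported gating matrix matches.  At K = 1 the procedure reduces to
   extra refit epochs, so the no-mixture reference shares the full
   training budget.

The MinCUT term is the standard differentiable relaxation
−Tr(WᵀAW)/Tr(WᵀDW) + ‖WᵀW/‖WᵀW‖_F − I_K/√K‖_F; it is −1 exactly when
clusters are unions of connected components with one-hot W.

Kinetic quantities (tendency, dynamical loss, velocities) operate on
first-order graph moments (closed-neighborhood means) of the
size-normalized linear-scale counts; the encoder consumes log1p
features.  Per-cell size factors are median/total multipliers on U+S.

### Choosing K

`select_num_experts` trains short runs over candidate K values, records
mean gating entropy, and picks the elbow of the (K, H) curve (maximum
chord distance; elbows under 1% of the range are flagged weak).  At
desk scale the short sweeps give noisy curves, so the fixed default
K = 8 is recommended unless the sweeps can be afforded at full length;
the benchmarks in this repository use the fixed K.

## Synthetic data

The simulator is exact: piecewise-constant rates with closed-form
trajectories chained across breakpoints, so ground-truth velocities
satisfy the ODE identities to machine precision.

* **Bifurcating lineage** (defaults 2000 cells × 1000 genes; the
  benchmarks here use 600 × 200 to stay desk-scale): uniform true time
  on [0,1], a 50/50 lineage split acting after t_b = 0.4, four gene
  pattern families in equal proportion — circular (α on/off: induction
  then repression, the classic almond-shaped phase portrait),
  sequential (three α levels at fixed breakpoints), branching
  (lineage-specific α and sometimes γ after t_b), independent
  (unrelated constant kinetics per lineage).  A cell's 4-way regime
  label crosses its time phase (pre/post t_b) with its lineage.
* **Spatial fields**: lattice cells; bilinear (two half-planes with
  linear time along distinct directions) or multi-radial (time =
  distance to nearest seed); each region has its own rate set.
* **Single regime**: constant per-gene rates; the identifiability
  baseline.

Rates are drawn from α ∈ [1,5], β ∈ [0.2,1], γ ∈ [0.1,0.7] per
ODE-time unit and the unit latent-time axis spans `time_span = 20`
ODE-time units — on a unit span these ranges leave trajectories
undeveloped (no closed loops, noise-dominated U–S correlation).
Default noise is Poisson resampling of abundances.  Truth (time,
rates, velocities, regimes, lineages) is recorded before noise.

Not emulated: sequencing-depth variation, ambient RNA, dropout beyond
Poisson sparsity, batch effects, doublets.  Passing these benchmarks
shows the machinery recovers planted kinetics from clean count noise;
it does not certify behavior under real-data artifacts.

## Evaluation

Velocity cosine (per cell across genes or per gene across cells; zero
vectors excluded and counted), Spearman latent-time correlation,
cross-boundary directionality (boundary cell = cell of population A
with ≥ 1 graph neighbor in B; cosine of its velocity with the mean
displacement toward those neighbors, in expression space), local
coherence (mean cosine with neighbors' velocities), Moran's I (spatial
kNN weights, k = 8, row-standardized by default), ARI.  Protocol
choices for the bundled benchmarks: spatial-ablation fields are
compared on a *common* reference neighborhood (the spatial kNN graph) —
comparing each model on its own graph conflates field quality with
graph smoothness; CBDir transitions on spatial simulations run between
consecutive quartile bins of true time; the expression-clustering
baseline for regime recovery is K-means on the top-30 PCs of
size-normalized log1p counts at the same cluster count as the model.

## Differential kinetic genes

Per gene and rate, a two-sided Wilcoxon rank-sum test between two cell
groups, BH-adjusted within each rate across genes (q < 0.05); rank-sum
is robust to heavy-tailed rate estimates.  Categories count significant
rates (SDR/DDR/TDR).  DDR pairs combining α and γ are *synchronous*
when sign(Δα) = −sign(Δγ) (both push steady-state expression
s_ss = α/γ the same way); β-involving pairs are asynchronous by
convention since β cancels from s_ss.  Directions use group-median
differences.  The DEG test is the identical procedure on spliced
expression.  Overlap percentages round half-away-from-zero.  The
time-pattern classifier (Growth/Peak/Recession/Trough/Flat) bins
expression along latent time (5 equal-count bins) against a tolerance
of 10% of the mean absolute level.

## Numerical and degenerate-input choices

* β = γ within a simulator piece is perturbed by 1e−6 (the closed form
  divides by γ − β).
* Gene-ranking ties break by ascending index; argmax routing ties break
  toward the smaller expert index.
* Cells with zero total counts get size factor 1 and are reported;
  genes with all-zero spliced counts get zero tendency columns; cells
  with zero velocity are excluded from cosine metrics and get zero
  projection arrows.
* An empty graph makes the MinCUT cut term 0 by definition.
* Divergence (non-finite objective) aborts with an error naming the
  stage.

## What the benchmarks do and do not show

On the bundled bifurcating simulation the full model recovers velocity
directions (mean cell cosine ≈ 0.75–0.85 against a noise ceiling of
≈ 0.94), an essentially exact time ordering (|Spearman| ≈ 0.98), and
regime assignments that track the planted structure about as well as —
and depending on the draw, better than — expression K-means.  Two
comparisons deserve honesty:

* The K = 1 reference is *strong* here, because half the simulated
  genes share kinetics across lineages and a well-initialized
  time-resolved single regime captures them perfectly.  The mixture's
  advantage on this generator is regime decomposition and per-regime
  kinetics, not necessarily bulk velocity cosine.
* Local spatial coherence rewards smooth fields; a regime-free model
  whose rates depend on time alone produces an extremely smooth (and
  directionally poorer) field, so coherence alone can rank a worse
  model higher.  Directional metrics (CBDir, cosine) are the ones that
  reflect correctness.

## Known limitations

* Full-graph training targets desk-scale data (≲ 10⁴ cells on one
  CPU); no minibatching.
* Routing is per cell; genes in one cell share a regime.
* The latent time is global; asynchronous per-gene clocks are averaged.
* The forward-difference loss assumes locally dense sampling along
  progression.
* Entropy-elbow K selection needs converged sweeps to be reliable.
* Transfer (`predict`) assumes the same gene set; graph and moments are
  rebuilt, parameters reused as-is.
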