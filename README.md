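# steer

Regime-aware RNA velocity inference for single-cell and spatial
transcriptomics.

RNA velocity estimates where each cell is heading by comparing its
unspliced (U) and spliced (S) mRNA under the splicing kinetics

    dU/dt = α − β·U         (transcription α, splicing β)
    dS/dt = β·U − γ·S       (degradation γ)

Classical velocity tools assume one kinetic law shared by all cells.  In
real tissues several kinetic regimes coexist — lineages switch
transcription programs, spatially adjacent domains follow opposite
dynamics — and single-regime fits blur or invert the resulting vector
fields.  `steer` addresses this with two coupled components:

* a **graph-attention autoencoder** over a unified cell graph
  (expression-similarity kNN, plus spatial-proximity kNN when tissue
  coordinates exist) that learns a latent state `z` and a per-cell
  kinetic time `t`, regularized for smoothness and for agreement with
  local transcriptional tendencies; and
* a **gated mixture of experts**: each expert network represents one
  kinetic regime as a family of per-gene rate curves over latent time,
  t → (α, β, γ); a soft gating network on `[z‖t]` routes cells across
  experts (so the latent state shapes rates through the regime
  assignment, per the kinetic law), with a MinCUT graph regularizer and
  a residual-driven EM refinement keeping the routing topologically
  coherent.  A forward-difference dynamical loss ties the learned rates
  to the expression changes actually observed between each cell and its
  later-in-time graph neighbors.

Outputs per cell: latent time, expert (regime) assignment, gating
distribution, full rate matrices, and velocity fields `v_u = α − βU`,
`v_s = βU − γS`, plus 2-D projected arrows for embedding or tissue
coordinates.  The package ships an exact multi-regime simulator
(bifurcating lineages, bilinear/multi-radial spatial time fields),
evaluation metrics (velocity cosine, latent-time correlation, CBDir,
local coherence, Moran's I, ARI), and differential kinetic gene (DKG)
analysis with SDR/DDR/TDR categories and DEG overlap statistics.

Audience: computational biologists who want regime-resolved velocity on
desk-scale data (hundreds to a few thousand cells/spots) and a fully
inspectable, pure-scientific-Python implementation.  Everything is
driven by explicit seeds and runs full-batch on one CPU; the neural
components run on a small bundled reverse-mode autodiff engine, so there
is no GPU or deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from steer import simulate_bifurcation, fit, TrainConfig
from steer import velocity_cosine, time_correlation, ari

# bifurcating lineage, four kinetic regimes, Poisson counts
data, truth = simulate_bifurcation(n_cells=600, n_genes=200, seed=11)

model = fit(data, TrainConfig(seed=1))          # three-stage training
gi = np.array([list(data.gene_names).index(g) for g in model.gene_names])

_, cos, _ = velocity_cosine(model.velocity()[1], truth.v_s[:, gi])
rho = time_correlation(model.t, truth.true_time)
a = ari(model.experts_of_cells, truth.regime_labels)
print(f"velocity cosine {cos:.3f}  time Spearman {rho:.3f}  regime ARI {a:.3f}")
```

On this simulation the run prints

```
velocity cosine 0.752  time Spearman 0.983  regime ARI 0.465
```

meaning: the per-cell velocity vectors point within ~40° of the
ground-truth direction on average (against a noise ceiling of ≈ 0.94
set by the Poisson counts), the inferred latent time reproduces the
true ordering almost perfectly, and the expert assignment recovers a
large share of the planted regime structure (ARI of 8 experts against
4 true regimes; oversplitting bounds it well below 1).

The same workflow is available from the shell:

```bash
steer simulate --scenario bifurcation --n-cells 600 --n-genes 200 --seed 11 --out sim.h5ad
steer fit --input sim.h5ad --seed 1 --out model/
steer predict --model model/ --input sim.h5ad --out results.h5ad
steer evaluate --pred results.h5ad --truth sim.h5ad --metrics cosine,time,ari --out report.json
steer dkg --input results.h5ad --groupby expert --groups 1,2 --out dkg.csv
```

## Layout

| module | role |
|---|---|
| `steer.io_data` | `VelocityDataset` container, h5ad/MTX IO, normalization, HVG and informative-gene filters |
| `steer.graph` | expression/spatial kNN graphs, union graph, moment smoothing |
| `steer.gaae` | graph-attention autoencoder with attention reuse |
| `steer.temporal` | time encoder, tendency field, smoothness/directionality losses |
| `steer.moe_kinetics` | gating, experts, MinCUT loss, entropy-elbow K selection |
| `steer.training` | three-stage orchestration, dynamical loss, save/load |
| `steer.velocity_analysis` | velocity fields, 2-D projection, DTW alignment |
| `steer.simulate` | exact piecewise-kinetic simulator (bifurcation/spatial/single-regime) |
| `steer.evaluate` | cosine, Spearman, CBDir, coherence, Moran's I, ARI |
| `steer.dkg` | rank-sum rate tests, SDR/DDR/TDR categories, overlap stats, time patterns |

See `docs/methods.md` for the model, loss, and simulator details and
the reasoning behind every default.
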