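# boostae

Sparse, interpretable dimensionality reduction for transcriptomics (bulk
and single-cell) with a **boosting autoencoder** (BAE): an autoencoder
whose linear encoder is fitted by componentwise likelihood-based L2
boosting instead of gradient descent.  Each latent dimension ends up
linked to a small, explicit set of genes — the nonzero entries of a
sparse encoder weight matrix — so the learned representation can be read
as a collection of candidate marker-gene programs.  The intended users
are computational biologists who want a latent space where every
dimension comes with the genes that explain it, including for very small
cell groups that a global clustering would miss.

## Model

Given a standardized expression matrix **X** ∈ ℝ^{n×p} (cells × genes,
z-scored per gene with the corrected (n−1) estimator), the model is

- **encoder**: Z = X B with a sparse B ∈ ℝ^{p×d}, no bias, identity
  activation;
- **decoder**: x̂ = W⁽²⁾ tanh(W⁽¹⁾ z + b⁽¹⁾) + b⁽²⁾, hidden width p,
  trained by Adam on the mean squared error
  L(x, x̂) = (1/p) Σ_j (x_j − x̂_j)².

B starts at zero.  In each epoch and for each latent dimension l, the
*pseudo-response* ĝ⁽ˡ⁾ is the standardized negative gradient of the
batch-mean reconstruction loss with respect to z⁽ˡ⁾.  One componentwise
boosting step then selects the gene
j\* = argmax_j ((x⁽ʲ⁾)ᵀ(ĝ⁽ˡ⁾ − η))² and updates only
β_{j\*} ← β_{j\*} + ε·γ with the closed-form least-squares coefficient γ
and a small step size ε, so after N epochs B has between d and d·N
nonzero entries.

Two refinements implement structural assumptions:

- **disentanglement constraint** — before boosting dimension l, ĝ⁽ˡ⁾ is
  replaced by the standardized residual of its OLS projection onto the
  other populated latent dimensions, so newly selected genes carry
  complementary information and the dimensions decorrelate;
- **timeBAE** — for T-snapshot time series, one BAE per time point,
  where the encoder at time t is initialized at the running delta
  B̃⁽ᵗ⁺¹⁾ = B⁽ᵗ⁾ − B̃⁽ᵗ⁾ of previous trainings (decoders freshly
  randomized).  Concatenating the deltas gives a p × d·T encoder whose
  column k + (t−1)d tracks developmental trajectory k at time t.

Interpretation utilities cover top-gene extraction by a change-point
criterion on sorted |weights|, quantile-threshold matching of dimensions
to cell labels, kNN label transfer for held-out cells, selection
stability counts across runs, latent Pearson correlations, and a
supervised OLS/Bonferroni regression baseline for gene selection.
Simulators for binary Bernoulli group designs (a stair-like single-time
design and a three-lineage, three-time-point design) generate all test
data.

## Worked example

```python
import numpy as np
from boostae import (TrainConfig, default_timeseries_design, simulate_binary_groups,
                     standardized_bundle, top_genes_changepoint, train_timebae)

design = default_timeseries_design()          # 3 lineages x 3 time points, 80 genes
bundle = simulate_binary_groups(design, seed=1)
mats = [s.values for s in standardized_bundle(bundle)]

cfg = TrainConfig(latent_dim=3, n_epochs=9, mode="jointLoss", batch_size=198, seed=1)
result = train_timebae(mats, cfg)
print("latent dimensions:", result.B_full.shape[1])
for c in (0, 1, 2):
    entry = top_genes_changepoint(result.B_full[:, c], bundle.gene_ids)
    print(f"dimension {c + 1} top genes:", entry.top_genes)
```

Output:

```
latent dimensions: 9
dimension 1 top genes: ['gene_52']
dimension 2 top genes: ['gene_28']
dimension 3 top genes: ['gene_11']
```

The timeBAE assembles 3 dimensions per time point into 9 overall.  Each
first-time-point dimension has latched onto one simulated lineage and
reports genes from its highly-expressed blocks: gene 52 lies in lineage
3's index range (41–58), gene 28 in lineage 2's (21–38) and gene 11 in
lineage 1's (1–18).

The same workflow is available from a shell:

```bash
boostae simulate --design table1 --seed 1 --outdir out/sim
boostae train --input out/sim/standardized_t1.csv -d 3 --epochs 9 \
    --mode jointLoss --batch-size 198 --seed 1 --outdir out/fit
boostae interpret --encoder out/fit/encoder_B.csv \
    --input out/sim/standardized_t1.csv \
    --labels out/sim/standardized_t1.labels.csv --outdir out/report
```

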