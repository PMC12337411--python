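# spatialvelo

RNA velocity inference for multi-batch spatial transcriptomics.

RNA velocity predicts where each cell is headed in expression space from
the instantaneous balance of unspliced and spliced mRNA: for each gene,
`v = beta u - gamma s`, with splicing rate `beta` and degradation rate
`gamma`, under four-state splicing kinetics (induction → induction steady
state → repression at a gene-specific switching time → repression steady
state). Standard velocity methods look at expression alone; spatial
transcriptomics adds two kinds of structure that they ignore — where each
cell sits in the tissue, and which slide (batch) it came from. This
package is for analysts with multi-batch spatial datasets (cell × gene
spliced/unspliced matrices, 2-D coordinates, batch labels in an h5ad
container) who want velocities, latent times, kinetic rates and
transcriptional states that are consistent across batches and informed by
spatial context.

The model is a deep generative one. Each cell's latent state
`z = z_VAE + z_GAT` sums an amortised Gaussian encoding of its scaled
unspliced/spliced profile with a graph-attention encoding over a combined
cell graph: spatial k-nearest-neighbour edges within each batch, plus
cross-batch mutual-nearest-neighbour edges whose affinity is
optimal-transport coupling mass. From `z`, neural heads produce a
Dirichlet posterior over the four transcriptional states per cell-gene and
latent times on each kinetic branch; observations are Gaussian mixtures
around the closed-form kinetic means. Training minimises

    L = L_ELBO + lambda * L_switch + lambda * L_batch,    lambda = 2,

where `L_switch` anchors each gene's switch point at the median expression
and `L_batch` is the squared maximum mean discrepancy between the batches'
latent distributions (Gaussian kernel), aligning batches in latent space.
The package also provides the velocity evaluation suite (confidence /
transition / direction scores over expression, spatial and MNN
neighbourhood graphs plus cross-batch coherence), latent-entropy
uncertainty, spatial ligand–receptor communication scores and their
velocity time derivative with permutation FDR, in-silico gene deletion,
and velocity-marker selection — everything runs on synthetic data with
known ground truth generated from the model's own kinetics.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from spatialvelo import (SimConfig, simulate, preprocess, PreprocessConfig,
                         SpatialVelocityModel)
from spatialvelo.evaluation import score_dataset

dataset, truth = simulate(SimConfig(n_cells_per_batch=200, seed=0))
processed = preprocess(dataset, PreprocessConfig())

model = SpatialVelocityModel(epochs=150, seed=0)
model.fit(processed)
velocity = model.predict(processed)

sub = truth.subset(processed.adata.var_names, dataset.gene_names)
print(spearmanr(sub["ratio"], model.rate_ratio(processed)).statistic)
report = score_dataset(processed, velocity, truth.transition_pairs, seed=0)
```

Output (abridged):

```
SpatialVeloDataset(400 cells x 90 genes, 2 batch(es), cell_type present, stage=raw)
SpatialVeloDataset(400 cells x 33 genes, 2 batch(es), cell_type present, stage=scaled)
velocity matrix: (400, 33)
gamma/beta recovery (Spearman): 0.930
latent-time recovery (Spearman): 0.810
direction score: 0.075  confidence: 0.800  coherence: 0.590
```

Reading the numbers: the simulator drew 30 dynamic genes (plus 60
steady-state background genes) across two 200-cell batches; preprocessing
kept 33 velocity genes. The fitted degradation/splicing ratios `gamma/beta`
rank-correlate with the simulation truth at 0.93, and the inferred latent
time orders cells along the true trajectory at 0.81. The evaluation scores
summarise how well velocities point along the planted cell-type
transitions: confidence 0.80 means velocities of neighbouring boundary
cells agree strongly; coherence 0.59 means velocities of matched cells
agree across batches; the direction aggregate is positive (it penalises
reversed transitions, and its ceiling under these study conditions is
modest — see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```sh
spatialvelo simulate --out raw.h5ad --seed 0
spatialvelo preprocess raw.h5ad --out pp.h5ad
spatialvelo fit pp.h5ad --out fitted.h5ad --epochs 300 --seed 0
spatialvelo evaluate fitted.h5ad --pairs pairs.csv --out scores.json
spatialvelo ccc fitted.h5ad --ligand gene_0 --receptor gene_1 --out ccc
```

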