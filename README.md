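# mogcan

Two-stage multi-omics cancer-subtype classification:

1. **Feature learning** — for each omics view, a patient affinity graph is
   built with a scaled exponential similarity kernel on squared Euclidean
   distances, sparsified by *dynamic threshold selection* (the smallest
   retention fraction on a `p0 + k·step` grid whose degree matrix is full
   rank), and used by a supervised two-layer graph convolutional network
   (GCN). The first convolution layer's activations serve as latent
   features.
2. **Classification** — the per-view affinity matrices are merged by
   similarity network fusion (SNF); the fused network is sparsified with
   the same threshold-selection routine and, together with the
   concatenated (and z-scored) latent features, drives a two-head graph
   attention network (GAT) with a softmax head. Training is transductive:
   all samples appear in every graph, but only training rows enter any
   loss.

Everything is plain NumPy/SciPy — the networks are small enough that the
forward and backward passes are hand-written and verified against scalar
per-node oracles and numerical gradients in the test suite.

## Layout

| module | contents |
| --- | --- |
| `mogcan.io_preprocess` | matrix/label readers, deduplication, NA filtering (features with >10% missing dropped, remaining NA→0), sample alignment, stratified 75/25 split |
| `mogcan.affinity_graph` | kernel affinity, top-percentile sparsification, row-normalized Laplacian, dynamic threshold selection |
| `mogcan.gcn_features` | per-omics GCN (2 conv + linear, ELU, dropout, Adam), latent extraction, omics selection, concatenation |
| `mogcan.snf_fusion` | SNF normalization, K-NN local affinity, cross-diffusion fusion |
| `mogcan.gat_classifier` | attention coefficients, two-head GAT forward/training, metrics (accuracy, macro P/R/F1, confusion) |
| `mogcan.synthetic_fixtures` | seeded multi-view generators (class-mean shifts, complementary views, NA injection, imbalance) and a fixed toy worked example |
| `mogcan.pipeline` | end-to-end orchestration, retention sweep, YAML config front end |

## CLI

```bash
# generate a synthetic dataset
mogcan simulate --config sim.yaml --outdir data/

# run the full pipeline
mogcan run --config cfg.yaml

# sweep edge-retention levels
mogcan sweep --config cfg.yaml --p-grid 0.01,0.11,0.21,0.31,0.41

# recompute metrics for saved predictions
mogcan evaluate --pred out/predictions.tsv --truth data/labels.csv
```

A minimal pipeline config:

```yaml
omics:
  mrna: data/omics0.tsv
  meth: data/omics1.tsv
labels: data/labels.tsv
delimiter: "\t"
seed: 7
outdir: out
# optional overrides (defaults shown)
mu: 0.5
k_neighbors: 20
p0: 0.01
step: 0.005
train_fraction: 0.75
latent_layer: 1          # 1, 2 or "output"
gcn: {hidden: 100, dropout: 0.5, lr: 0.001, weight_decay: 0.01}
gat: {n_heads: 2, head_dim: 100}
```

Run outputs land in `outdir`: `metrics.json`, `predictions.tsv`,
`confusion.tsv`, `fused_network.tsv`, `latents/*.tsv`, `run_record.json`.
Runs are bit-reproducible given the same config and seed.

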