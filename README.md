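# metastagraph

Interpretable low-dimensional embeddings of **time-evolving graphs with
metastable dynamics** — graph sequences that linger in one configuration
regime for long stretches and rarely hop to another, the way a microbial
community lingers in a "healthy" co-occurrence regime and occasionally
shifts to a "diseased" one.

The package is aimed at researchers in microbial ecology and network
inference who want to (1) compress a sequence of graph snapshots
G_1, …, G_T on a fixed node set into vectors ĝ_1, …, ĝ_T ∈ R^d that
preserve the state structure, (2) recover the states by clustering the
embedding, and (3) ask *which nodes* made two states different.

## What's inside

* **`metastagraph.dynamics`** — Euler–Maruyama simulation of the overdamped
  Langevin SDE dX = −∇V dt + √(2/β) dW in an s-well ring potential or the
  scalar double well V(x) = x⁴/4 − x²/2, with ground-truth well labels.
* **`metastagraph.graphgen`** — turns a trajectory into a benchmark graph
  sequence with planted state-discriminating features (positional and
  non-positional variants).
* **`metastagraph.otu`** — microbiome path: co-occurrence base graph from
  an OTU count table (|Pearson r| ≥ threshold) with per-sample zero-count
  edge masking, plus a synthetic OTU fixture with hidden regimes.
* **`metastagraph.model`** — `GraphContrastiveEmbedder`, a scikit-learn
  style estimator: a 3-layer, 4-head transformer encoder whose attention
  is masked by each snapshot's adjacency matrix, pooled through a
  recurrent *master node* carried over sliding windows of length l = 3,
  projected to R^d and trained with the InfoNCE objective

      L = −log  exp(ĝ_t·ĝ_{t+1}/τ) / Σ_{i=1}^B exp(ĝ_t·ĝ_i/τ),

  where the positive for time t is its temporal successor t+1 — under
  metastability almost surely of the same state.
* **`metastagraph.interpret`** — per-node relevance via gradient-weighted
  attention rollout, aggregated per metastable state.
* **`metastagraph.evaluate`** — k-means + Adjusted Rand Index on a held-out
  temporal split, an `AdjacencyPCA` baseline on flattened adjacency
  matrices, and transition-matrix diagnostics.
* **`metastagraph.cli`** — a `metastagraph` console command orchestrating
  generate → train → embed → evaluate → interpret with named presets.

The model itself is implemented on a small NumPy reverse-mode autodiff
engine (`metastagraph.autodiff`) written for this package; gradients of
every primitive are tested against finite differences.

## Worked example

```bash
metastagraph generate --preset demo --seed 1 --out demo_data
metastagraph train    --data demo_data --out demo_run
metastagraph embed    --data demo_data --model demo_run/model.npz --out demo_run/embeddings.csv
metastagraph evaluate --data demo_data --embeddings demo_run/embeddings.csv --out demo_run/report.json
metastagraph evaluate --data demo_data --method pca --d 8 --out demo_run/pca_report.json
```

which prints (numbers from this exact command sequence, about half a
minute end to end):

```
wrote 600 snapshots (20 nodes, 2 states) to demo_data
trained demo: loss 3.1983 -> 0.0134
wrote 600 x 4 embeddings to demo_run/embeddings.csv
demo [model] ARI=0.870 stay=0.896
demo [pca] ARI=0.807 stay=0.875
```

The `demo` preset simulates a double-well trajectory (600 steps), plants a
state-dependent degree pattern on 20 nodes, trains briefly, and evaluates
on the last 20% of the sequence. The model's ARI of 0.87 means k-means on
the embeddings recovers the ground-truth wells up to a few boundary
snapshots (and here slightly beats the PCA baseline's 0.81);
`stay=0.896` is the empirical probability that consecutive test snapshots
stay in the same cluster — close to 1, i.e. the embedding preserved the
metastability. The benchmark presets (`npos_2well`, `pos_2well`,
`pos_3well` at T = 10000, and their `*_small` counterparts at T = 2000,
minutes on one core) work the same way; see
`metastagraph.presets.PRESETS`.

As a library:

```python
from metastagraph import get_preset, generate_dataset, GraphContrastiveEmbedder
from metastagraph.evaluate import evaluate_embedding, temporal_split

cfg = get_preset("npos_2well_small", seed=1)
g = generate_dataset(cfg)                      # TimeEvolvingGraph, T=2000, n=50
train_sl, test_sl = temporal_split(g.T, 0.8)
model = GraphContrastiveEmbedder(**cfg.model, seed=0).fit(g.subsequence(train_sl))
emb = model.transform(g)                       # (2000, 32)
print(evaluate_embedding(emb, g.states, k=2, test_index=test_sl).ari)
```

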