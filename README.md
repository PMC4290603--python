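# smcc — semi-supervised multi-label collective classification on attributed networks

`smcc` predicts the functional classes of nodes in a partially labeled,
attributed interaction network — the canonical use case being protein
function and localization prediction from a protein–protein interaction
(PPI) network in which only a few percent of proteins carry annotations.
It is aimed at computational biologists who have (a) an undirected
interaction network, (b) categorical or count-valued node attributes, and
(c) multi-label annotations for a small subset of nodes, and who want
calibrated per-node label probabilities plus relevant-label sets for the
rest.

## The model

The core model (GM-SMCC) is a pLSA mixture whose latent variables are the
`K` functional classes: with `n(x_i, w_j)` the count of attribute word
`w_j` on node `x_i`, the data log-likelihood is

    L = Σ_i Σ_j n(x_i, w_j) log Σ_k P(w_j | c_k) P(c_k | x_i)

and the fitted objective adds two symmetric-KL smoothness penalties,

    O = L − α R − β H

* `R = Σ_{i,s} D(z_i, z_s) E_is` — the **network regularizer**: linked
  nodes should have similar class distributions `z_i = P(· | x_i)`
  (homophily assumption);
* `H = Σ_{k,l} D(r_k, r_l) F_kl` — the **label regularizer**: classes with
  high cosine co-occurrence `F_kl` among the labeled nodes should have
  similar per-node probability profiles `r_k`.

Fitting is EM. The E-step and the `P(w|c)` M-step are the standard pLSA
updates; the `P(c|x)` M-step solves a sparse symmetric linear system
`(Ω + α(D−B) + β(U−R)) y = Z` combining posterior-weighted counts with the
graph and label Laplacians. Labeled nodes are clamped to a uniform
distribution over their known labels at every iteration, so supervision
propagates outward through the network. Per-node relevant-label sets are
cut at the largest gap in the sorted probabilities.

The ensemble extension (EGM-SMCC) fits one GM-SMCC per *latent graph* —
the observed network, an even-step random-walk-with-restart graph, and a
kNN graph over one-vs-rest classifier confidence vectors — and averages
the probability tables.

## Worked example

```python
import numpy as np
from smcc import GMSMCC, EGMSMCC, SyntheticConfig, generate
from smcc.metrics import top1_accuracy

# homophilous network, 300 nodes, 6 classes, 5% labeled
ds, truth = generate(SyntheticConfig(seed=1, single_label=True))
test = ~ds.labeled_mask

plsa = GMSMCC(ds, alpha=0.0, beta=0.0).fit()
smcc = GMSMCC(ds, alpha=3.0, beta=0.0).fit()
print("features only :", round(top1_accuracy(plsa.scores[test], truth[test]), 3))
print("with network  :", round(top1_accuracy(smcc.scores[test], truth[test]), 3))
print(smcc.summary())
```

prints

```
features only : 0.674
with network  : 0.786
GM-SMCC fit summary
===================
nodes: 300  features: 40  classes: 6
labeled: 15 (5.0%)
alpha: 3  beta: 0
iterations: 15  converged: True
objective: -36764.8817  loglik: -32364.9142
network penalty: 1466.6558  label penalty: 0.0000
mean predicted label cardinality: 1.57
```

i.e. on this draw, smoothing the class distributions over the network
lifts test accuracy from 0.674 to 0.786 with 15 labeled nodes; the
objective trace (`smcc.objective_trace`) records `(O, L, R, H)` per EM
iteration. `res.predict_labels()` returns a `ScoreTable` whose
`relevant_sets` hold the gap-thresholded label sets, and
`EGMSMCC(ds).fit()` runs the three-graph ensemble.

The same pipeline is available from the shell:

```sh
smcc simulate --config sim.yaml --out-prefix data/
smcc fit --edges data/edges.tsv --features data/features.tsv \
         --labels data/labels.tsv --encoding counts \
         --alpha 3 --beta 0.1 --graphs ppi,rwr,predsim --out scores.tsv
smcc eval --scores scores.tsv --truth data/truth.tsv \
          --metrics coverage,rankingloss,macrof1
```

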