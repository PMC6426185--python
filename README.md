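# surewalk

Node prioritization in networks by random walks with **node-specific,
learned restart probabilities**.

## The problem

Given a graph (a protein-interaction network, a citation or collaboration
network, a hyperlink network), a standard way to score every node's
relevance to a query node *s* is the random walk with restart (RWR, a.k.a.
personalized PageRank): a surfer follows out-edges with probability
1 − *c* and teleports back to *s* with probability *c*. Two limitations
follow: the single global *c* cannot encode that the query "likes" some
regions of the graph and "dislikes" others, and *c* itself has to be
picked by hand.

`surewalk` implements the extended model in which every node *i* carries
its own restart probability *c*<sub>*i*</sub>. With row-normalized
adjacency **Ã**, restart vector **c**, and seed distribution **q**, the
score vector **r** solves the fixed point

```
r = Ãᵀ (I − diag(c)) r + (cᵀ r) q
```

which has the closed form **r** = (**I** − **B**)⁻¹**q** with
**B** = **Ã**ᵀ(**I** − diag(**c**)) + **q**(**c** − **1**)ᵀ. A constant
**c** recovers classical RWR; **c** = **1** collapses to **r** = **q**.

The restart vector is *learned* from side information — a set *P* of
nodes the query prefers and a set *N* it dislikes — by minimizing the
regularized pairwise ranking cost

```
F(c) = λ‖c − o‖² + Σ_{x∈P, y∈N} h(r_y − r_x),     h(t) = 1/(1 + e^{−t/b})
```

with projected gradient descent. The gradient is assembled from one
forward walk solve and one adjoint linear solve
(**I** − **B**ᵀ)**r̃** = **p̃** (GMRES), so each step costs O(*m*) per
inner iteration — no matrix inversion.

The package also ships ranking metrics (MAP, pairwise AUC, precision@k),
neighborhood baselines (common neighbors, Adamic–Adar, Jaccard), seedable
synthetic scenario generators (two-community labeled graphs;
triangle-closing temporal collaboration graphs with time-split
link-prediction instances), and a CLI.

## Worked example

```python
import numpy as np
from surewalk import LearnConfig, learn_restart, row_normalize, rwer_power, rwr, seed_vector
from surewalk.evaluation import auc_pairwise
from surewalk.synthetic import generate_sbm, make_ranking_instance

# two-community graph: 100 + 100 nodes, within-rate 0.1, cross-rate 0.02
scn = generate_sbm(100, 100, p_in=0.1, p_out=0.02, rng_seed=7001)
ri = make_ranking_instance(scn, query=17)       # neighbors -> P / N by community
At = row_normalize(scn.graph)
q = seed_vector(scn.graph.n, ri.instance.seed)

res = learn_restart(At, ri.instance, LearnConfig(rng_seed=1, max_outer=60))
print(f"cost {res.cost_trace[0]:.2f} -> {res.cost_trace[-1]:.2f}")

r_learned = rwer_power(At, q, res.c).r
r_fixed = rwr(At, q, 0.15).r
pos = ri.test_nodes[ri.test_relevance == 1]
neg = ri.test_nodes[ri.test_relevance == 0]
print(f"held-out AUC learned {auc_pairwise(r_learned[pos], r_learned[neg]):.4f}"
      f" vs fixed-restart {auc_pairwise(r_fixed[pos], r_fixed[neg]):.4f}")
```

Output:

```
cost 51.62 -> 10.52
held-out AUC learned 0.7254 vs fixed-restart 0.6652
```

The learner drove the training cost down by a factor of five, and
the learned walk separates the query's community from the other one on
the held-out (non-neighbor) nodes better than the conventional fixed
restart probability 0.15.

The same pipeline from the shell:

```sh
surewalk simulate --scenario sbm --seed 7001 --out-dir scenario/
surewalk learn --graph scenario/edges.tsv --undirected --seed-node 17 \
    --labels my_labels.tsv --seed 1 --out-dir fit/
surewalk rank --graph scenario/edges.tsv --undirected --seed-node 17 \
    --restart-vector fit/restart.tsv --out-dir ranked/
surewalk evaluate --scores ranked/scores.tsv --labels test_labels.tsv --k 20 \
    --out-dir metrics/
```

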