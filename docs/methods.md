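# Methods

## Model

`surewalk` scores every node of a weighted graph by the stationary
distribution of a restarting random walk in which the restart probability
is a *vector*: at node *v* the surfer follows an out-edge (chosen with
probability proportional to edge weight) with probability 1 − c_v, and
teleports to the seed distribution **q** with probability c_v. With
**Ã** the row-normalized adjacency, the score vector solves

    r = Ãᵀ (I − diag(c)) r + (cᵀ r) q .

Using 1ᵀr = 1 this is a linear system: r = (I − B)⁻¹ q with
B = Ãᵀ(I − diag(c)) + q(c − 1)ᵀ. The equivalent walk operator
G = Ãᵀ(I − diag(c)) + qcᵀ is column-stochastic, so the fixed point is
the principal eigenvector of G: power iteration converges whenever the
chain is irreducible and aperiodic, and the restart mass at the seed
provides the aperiodicity as long as every c_i > 0. Constant **c**
recovers classical RWR / personalized PageRank; **c** = **1** returns
**q** itself.

Two solvers are provided. `rwer_power` is plain power iteration — one
sparse matrix–vector product per step, O(m) per iteration — which is the
production path. `rwer_closed_form` densifies (I − B) and solves
directly; it is guarded to n ≤ 2000 and exists as an independent oracle
for tests and gradients, not as a scalable solver.

### Numerical choices

- **Residual norm.** Convergence is declared on the L1 change
  ‖r′ − r‖₁ < ε, matching the probability-mass reading of the iterate.
  Default ε = 1e-10, max 1000 iterations (the learner raises the cap,
  since strongly "sticky" restart vectors slow mixing).
- **Start vector.** r⁰ = q. Any probability vector converges to the same
  fixed point; the seed distribution is the natural warm start and makes
  the c = 1 collapse exact in one step.
- **Renormalization.** The iterate is rescaled to unit mass whenever
  floating-point drift exceeds 1e-12; this guards long runs without
  changing the fixed point.
- **Dangling nodes.** Rows of Ã with zero out-degree are replaced by qᵀ
  (the surfer at a dead end teleports to the seed distribution with
  probability 1). This keeps G column-stochastic while leaving the
  recorded matrix untouched; the substitution is applied uniformly in the
  forward solve, the closed form, the operator, and the gradient, so all
  paths describe the same chain.
- **Restart clamp.** Learned restart vectors live in
  [c_min, c_max] = [0.001, 0.999] by default, keeping restart mass
  positive everywhere (aperiodicity) and edge-following possible.
  c = 1 is permitted for direct solves to support the analytic collapse.

## Learning the restart vector

Side information for a query *s* is a positive set *P* and a negative set
*N* (both disjoint from each other and from *s*). The restart vector is
fit by minimizing

    F(c) = λ‖c − o‖² + Σ_{x∈P, y∈N} h(r_y − r_x),   h(t) = (1 + e^{−t/b})⁻¹.

Each pair term lies in (0, 1) and decays as the positive outscores the
negative; with small *b* the sigmoid approaches the 0/1 pairwise ranking
loss whose expectation is 1 − AUC. The origin vector **o** anchors the
solution and prevents degenerate collapse of **c**.

The gradient is

    ∂F/∂c = 2λ(c − o) + ((−Ã + 1 e_sᵀ) r̃) ∘ r ,

where r̃ solves the adjoint system (I − Bᵀ) r̃ = p̃ and
p̃ = Σ_{x,y} h′(r_y − r_x)(e_y − e_x) aggregates the pair slopes on the
labeled nodes (its entries sum to zero exactly). The adjoint system is
non-symmetric and is solved matrix-free with GMRES; if the Krylov solve
does not reach the residual contract ‖(I − Bᵀ)r̃ − p̃‖₂ < solver_eps,
a dense solve takes over for n ≤ 2000, otherwise the failure is raised.
The whole derivative chain is validated in the test suite against
central finite differences of F and against a dense per-pair resolvent
derivative, both to tight tolerances.

### Optimizer

Projected gradient descent: c ← clip(c − η ∂F/∂c, c_min, c_max).
Design choices where the procedure is genuinely open:

- **Initialization**: uniform in the clamp range under `rng_seed`
  (an `init="origin"` option gives a deterministic start at **o**). In
  practice both starts reach the same minima on the synthetic scenarios.
- **Step size**: fixed η = 0.1 with accept/reject halving — if a step
  would increase the cost the step is halved (up to 30 times) before
  being taken. This prevents divergence without changing converged
  points; with halving disabled, five consecutive accepted cost
  increases raise an error advising a smaller η.
- **Stopping**: ‖Δc‖∞ < 1e-4 or 200 outer iterations.
- **Defaults** λ = 1 and b = 0.01 are the grid-search winners reported
  for this family of ranking/link-prediction tasks; o = 0.15 (the
  conventional RWR restart) broadcast to all nodes, user-configurable.
- Pair enumeration is exact (no subsampling): |P||N| is small in the
  intended use cases, entering the cost only additively.
- The gradient is evaluated at the clamped point; no correction is made
  for the projection's active set.

## Evaluation

`auc_pairwise` is computed by the rank-sum identity (ties count 1/2),
`average_precision`/`map_score` and `precision_at_k` operate on the
induced ranking only, with score ties broken by ascending node index.
Neighborhood baselines (common neighbors, Adamic–Adar with natural log,
Jaccard as |∩|/|∪|) use the undirected neighbor union on directed
graphs, since these heuristics are defined for undirected networks. The
heuristic restart vector `s_rwer_vector` assigns 0.1 to positives, 0.7
to negatives, and a configurable default (0.15) elsewhere.

## Synthetic scenarios

Two generators make every stage testable without external data. They are
pure functions of their parameters and an RNG seed.

**Two-community labeled graphs** (`generate_sbm`): a planted-partition /
stochastic-block graph with within-rate p_in and cross-rate p_out,
emulating a homophilous two-camp network such as a political-blog
hyperlink graph. Ranking instances take a query of degree ≥ 5 (the
protocol's "degree greater than 4"), label its same-community neighbors
positive and its cross-community neighbors negative, and hold out all
non-neighbors as test nodes labeled by community. The learning
benchmarks in the tests and the acceptance script use n = 100 + 100,
p_in = 0.1, p_out = 0.02, and 20 replicates — sizes chosen so the full
comparison completes in seconds while keeping ~10 within-community and
~2 cross-community neighbors per query, the sparse-side-information
regime the method targets.

**Triangle-closing temporal graphs** (`generate_temporal_collab`): from
a seed triangle, nodes join one per step by uniform attachment, and each
step adds internal edges that close a uniformly chosen open 2-hop pair
with probability β (else a uniform non-adjacent pair). With β = 0.8 the
majority of internal edges connect 2-hop pairs, reproducing the
empirical motivation for restricting link-prediction candidates to
2-hop neighbors. Link-prediction instances cut each query's incident
edge time span L at t1 = t_min + 0.3 L and t2 = t_min + 0.7 L:
neighbors gained in (t1, t2] are training positives; an equal number of
negatives is sampled uniformly without replacement among nodes ≥ 3 hops
away in the training graph; links after t2 to nodes exactly 2 hops away
in the training graph (which excludes the test links) are the test
positives within the 2-hop candidate set.

What the generators do *not* emulate: heavy-tailed degree sequences,
degree–community correlations, multi-scale community structure, or
realistic timestamp burstiness. Passing tests therefore demonstrate the
correctness of the machinery and the learner's advantage under clean
homophily, not performance on any particular real network.

### Observed behavior of the learning comparison

On the two-community scenario the learned restart vector consistently
reduces the training cost and raises the mean held-out AUC over the best
fixed restart probability from a 3-value grid ({0.05, 0.15, 0.5},
selected per replicate on the test AUC itself). Per-replicate wins
fluctuate: queries with a single cross-community neighbor give the
pairwise loss almost no signal, and on such instances a large constant
restart can win — the same weak-side-information regime in which fixed
restarts are reported competitive on real low-degree queries. The
acceptance check (≥ 15/20 wins, strictly greater mean) holds at the
suite's frozen conditions; the mean advantage is stable across seeds.

## Limitations

- The dense closed form and resolvent are O(n³)/O(n²) and deliberately
  guarded; they are oracles, not solvers.
- Power iteration slows as entries of c approach 0 (mixing rate is
  bounded by the restart mass along cycling paths); the learner's inner
  iteration cap is sized for the clamp default.
- The cost is non-convex; the optimizer finds local minima and makes no
  global claims.
- Learning assumes a single query per instance; multi-query (shared-c)
  training is out of scope, as are learned edge weights, learned
  topology, and attribute-parameterized restart probabilities.
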