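# Methods

This note records the model, the numerical conventions, the design choices
made where the construction was genuinely open, and what the synthetic
generator does and does not emulate.

## The similarity model

A weighted graph is stored as a dense symmetric matrix W with zero diagonal;
w_xy > 0 defines adjacency, k_x counts incident edges and s_x = Σ_y w_xy.
Self-loops are dropped on input (with a logged warning) and duplicate edges
keep the last weight seen; both policies are deterministic so that loading a
file twice yields identical objects. Disconnected graphs are accepted
throughout — no index here requires connectivity, and the random-walk family
handles isolated nodes with a self-loop row that keeps the transition matrix
row-stochastic.

The REDD chain is: structural triples (uw, dw, sw) → pairwise Euclidean
distances → probability vectors p(x,y) = 1 − d(x,y)/Σ_y d(x,y) → restriction
to the top-d unit-weight nodes, renormalized → symmetrized base-2 KL → 
s_xy = 1 − d_xy/d_max. Identical algebra backs RE-LRW (walk distributions,
top-d by degree) and LRE (closed-neighborhood degree histograms on the
union of observed degrees), so all three entropy-family indices share one
difference-to-similarity kernel.

### Numerical conventions

- **Logarithm base.** Base 2 everywhere in the entropy family. (One could
  equally use ln; the choice only rescales d_xy and cancels in d_xy/d_max
  except through the zero convention, which is scale-free anyway.)
- **Zero convention.** A KL term with p_z = 0 or q_z = 0 contributes 0.
  Consequence: each directed RE can be negative, but the symmetrized
  difference reduces to Σ (p_z − q_z) log2(p_z/q_z)/2 over coordinates where
  both are positive, each term ≥ 0, so d_xy ≥ 0 and s_xy ∈ [0, 1] always.
- **Degenerate distances.** If all triples coincide (any vertex-transitive
  uniform-weight graph: cycles, cliques, edgeless graphs), every distance
  sum is 0; the ratio is defined as 0, giving the all-ones full distribution,
  a uniform reduced distribution, d_max = 0, and the all-ones similarity
  matrix. Identical nodes are maximally similar, which is the only sensible
  limit of s = 1 − d/d_max as d → 0 everywhere.
- **Isolated nodes** get the all-zero triple (uw = dw = sw = 0) and are
  excluded from top-d rankings; a documented convention beats a crash, and
  the triple correctly marks them as carrying no weight.
- **Ties.** Top-d rankings (unit weight for REDD, degree for RE-LRW) break
  ties by ascending node index; the most-similar-node argmax breaks ties by
  lowest index. Both choices make every result bit-reproducible.
- **Self-membership.** When x is itself a top-d node, its own entry
  p(x, x) = 1 is retained before renormalization rather than excluded; the
  construction nowhere requires removing it, and keeping it preserves the
  unit-self-entry identity.
- **Accumulation** is double precision; test comparisons use absolute
  tolerance 1e−10 for whole-matrix equivalence and 1e−12 for scalar
  identities.

### Tunable parameters

| parameter | meaning | default | why |
|---|---|---|---|
| d | reduced-distribution dimension | 5 (valid 2..n) | midpoint of the 2–7 range that is worth sweeping; no single winner exists across networks, so `--d-range` sweeps are first-class |
| t | random-walk steps (LRW family) | 3 | the conventional local-walk horizon; longer walks blur locality |
| train_fraction | AUC training share | 0.9 | standard 90/10 probe split |
| replicates | AUC averaging runs | 30 | averages out split randomness |
| r | AUC comparisons per run | 10,000 | sampling error ≤ 0.5/√r = 0.005 |

AA uses the natural log (the conventional form); WAA uses log(1 + s_z) so
sub-unit strengths cannot flip the sign. The LRW/RE-LRW walk is unweighted
(P_xy = a_xy/k_x), matching the degree-based original; a weighted variant
(w_xy/s_x) sits behind the `weighted_walk` flag for sensitivity checks.
RE-LRW's final mapping to similarity is not uniquely pinned by its verbal
description; the 1 − d/d_max form is used for internal consistency with the
rest of the entropy family.

## Evaluation protocols

MS is computed on the full observed graph (it involves no randomness beyond
the index itself). AUC uses uniformly random edge partitions; the probe size
is round-half-up of (1 − fraction)·m, the unknown-edge universe is every
non-adjacent pair of the original graph, sampling is with replacement, and
replicate i uses seed base_seed + i. The similarity matrix for AUC is always
computed from the training graph; a regression test poisons probe-edge
weights and asserts the scores are unchanged. `auc_exact` (the exhaustive
rank statistic) is the oracle against which the sampled estimator is
validated. Splits are shared across indices within a replicate when several
indices are compared, so differences are never split noise.

## The synthetic generator

`nw_small_world` builds a ring lattice in which each node connects to its M
nearest neighbors **per side** (base degree 2M, n·M edges) and then adds a
shortcut to each non-adjacent pair independently with probability P; nothing
is rewired or removed. The per-side reading is chosen because the benchmark
suite's average degrees (≈ 6 at M = 2 plus sparse shortcuts) are of order 2M,
not M; a total-degree-M lattice is available via the alternative convention
flag in the suite parameters if needed. Shortcut counts are exactly
Binomial(n(n−1)/2 − nM, P), which the tests verify across seeds.

Edge weights come from a pluggable model. The default is **degree_product**:
w_xy = u · k_x · k_y with u ~ Uniform(1, 3). Rationale: across the nine
standard (M, P) settings, published mean strengths of comparable simulated
suites scale with the *square* of the mean degree (mean edge weight
≈ 2.1·⟨k⟩² at every density), which an i.i.d. weight model cannot produce
but a degree-product model reproduces naturally — strong ties attach to
well-connected endpoints, as in gravity-style models of transport networks.
`uniform_int` (integers on [1, w_max], default 165, matching the sparsest
setting's implied mean weight) and `constant` remain available.

### What the generator does and does not show

The generator reproduces small-world topology (high clustering at low P,
shortcut-driven shortening) and a realistic strength hierarchy. It does
**not** reproduce one property most real weighted networks have:
**assortative placement of edges with respect to node structure**. In
Newman–Watts graphs, which pairs become edges is independent of endpoint
degrees and strengths by construction. Any index that scores a pair purely
by the closeness of node-level summaries — REDD included — therefore has no
link-prediction signal here: measured exact AUC sits at 0.45–0.50 across
weight models and (M, P) settings, slightly *below* chance because removing
a probe edge perturbs both endpoints' strengths by differently-scaled shares
of the same weight, inflating their triple gap. This is a property of the
generator, not of the index: passing MS results on synthetic suites (REDD
attains the highest optimal-d MS of all eight indices, with no
general-similar-node pathology) transfer to real data, but synthetic AUC
results do not — on real networks the index's AUC comes from degree/strength
assortativity that this generator deliberately lacks. Neighborhood-overlap
indices (CN family, LRW) do score well here (AUC ≈ 0.8 at M = 2, P = 0.01)
because ring edges share common neighbors.

Reproducing any particular published suite's exact edge counts and mean
strengths is a non-goal: those are single stochastic realizations of an
under-specified generator (the published m values are also consistent with
ordered-pair shortcut trials, effective probability 2P − P², rather than the
unordered-pair trials used here).

## Problem sizes used in the tests

Whole-matrix oracle equivalence runs on 200 random graphs with n ∈ [4, 12];
divergence identities on 1000 random distribution pairs; estimator
consistency on 50 sampled-AUC runs at r = 10,000 on an n = 100 network;
generator statistics on 200 seeds; the end-to-end suite run uses n = 100
networks spanning the (M, P) grid with 10 replicate seeds. These sizes give
tight Monte-Carlo error bars (3σ bands throughout) while keeping the full
suite fast enough to run on every change.

## Known limitations

- Dense n×n storage: fine through a few thousand nodes, not for large
  sparse graphs (sparse shortcuts would change nothing mathematically but
  are deliberately out of scope).
- The LRE construction ("degree distribution of each node") follows the
  closed-neighborhood histogram reading; other readings exist in the
  literature.
- Directed graphs, multigraphs and negative weights are rejected, not
  coerced.
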