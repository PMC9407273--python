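# reddsim

Node-similarity measurement and link prediction for **weighted graphs**,
built around the REDD index — *relative entropy of distance distributions* —
together with seven benchmark indices and the two standard evaluation
protocols (mutual-most-similar-node mining and link-prediction AUC).

Weighted networks are everywhere in systems biology and beyond: protein
interaction strengths, food-web energy flows, neural connection counts,
air-transport volumes. Most classical similarity indices (common neighbors,
Adamic–Adar, local random walks) use only the *degree* k_x of a node — its
number of edges — and ignore its *strength* s_x = Σ_y w_xy, the total weight
it carries. REDD combines both.

## The method

For each node x of a weighted graph G = (V, E, W):

1. **Structural weight triple.** Three scalars summarize how x collects and
   diffuses information:

   - unit weight uw(x) = s_x / k_x (mean incident weight),
   - degree weight dw(x) = k_x² / (Σ_y k_y) · 1/s_x,
   - strength weight sw(x) = s_x² / (Σ_y s_y) · 1/k_x.

2. **Distance and probability distributions.** With the triple as a point in
   3-space, d(x, y) is the Euclidean distance between triples, and each node
   gets the probability vector p(x, y) = 1 − d(x, y)/Σ_y d(x, y): nearby
   nodes get probability close to 1. The full vector has unit self-entry and
   sums to n − 1.

3. **Top-d reduction.** Distributions are restricted to the d nodes of
   largest unit weight (the "top-d important nodes") and renormalized to sum
   to 1, which keeps the divergence computation d-dimensional regardless of
   graph size.

4. **Similarity.** The difference between two nodes is the symmetrized
   Kullback–Leibler divergence of their reduced distributions,
   d_xy = (RE(x,y) + RE(y,x))/2 with RE in base 2 and the per-term zero
   convention, and the similarity is

       s_xy = 1 − d_xy / d_max ∈ [0, 1].

Benchmark indices provided for comparison: CN, WCN, AA, WAA, LRW (3-step
local random walk), RE-LRW (relative entropy of walk distributions) and LRE
(relative entropy of closed-neighborhood degree histograms).

Evaluation: **MS**, the fraction of nodes that belong to a mutually-most-
similar pair, and **AUC**, the probability that a held-out probe edge
outscores a random non-edge, estimated over random 90/10 train/probe splits
with the index computed from the training graph only.

A Newman–Watts small-world generator (ring lattice plus random shortcuts,
pluggable edge-weight models) makes every pipeline testable without any
dataset downloads; loaders for weighted edge lists, Pajek `.net` files and
adjacency CSV cover the formats real datasets ship in.

## Worked example

```python
import reddsim as rs

# a weighted small-world network: 100 nodes, ring lattice M=2, shortcut
# probability P=0.05, degree-product edge weights
g = rs.generate(rs.NWParams(n=100, M=2, P=0.05, seed=42))
st = rs.topology_stats(g)
print(st.n, st.m, st.mean_degree, st.mean_strength)

sim = rs.redd_similarity_matrix(g, d=5)
print(rs.mutual_most_similar_ratio(sim))

res = rs.run_experiment(g, "redd", metric="auc", d=5, replicates=10)
print(res.value)
```

prints (abridged):

```
n=100 m=433 <k>=8.66 <s>=1445.3 <c>=0.162 rho=0.087
REDD MS (d=5): 0.6600
REDD link-prediction AUC (10 replicates): 0.4881
```

Reading the numbers: 66% of nodes sit in mutually-most-similar pairs under
REDD — the highest of all eight indices on this network, and the index shows
no "general similar node" pathology (no single hub attracts most nodes).
The link-prediction AUC on *this synthetic generator* hovers at chance,
because Newman–Watts edge placement is independent of the degree/strength
summaries REDD scores by — see `docs/methods.md` for what the generator can
and cannot show about real data, where degree/strength assortativity gives
the index its signal.

The same workflow from the shell:

```sh
reddsim synth --n 100 --m-param 2 --p-param 0.05 --seed 42 --out nw/
reddsim similarity --input nw/net.edgelist --index redd --d 5 --out out/
reddsim evaluate --input nw/net.edgelist --index redd --index wcn \
        --metric auc --replicates 10 --out results.csv
reddsim stats --input nw/net.edgelist
```

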