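# ricewalk

Candidate-gene prioritization by **random walk with restart (RWR)** on a
**functional similarity network**, with the cross-validation harness used to
tune and validate the restart parameter. The approach was developed for
finding rice (*Oryza sativa*) yield-related genes from a curated seed set on
a STRING protein-association network, but applies to any
guilt-by-association prioritization problem with a gene network, functional
annotations, and a seed list.

## Method

**Edge weighting.** Starting from an undirected protein-association edge
list, each edge (i, j) is scored by the *weighted shared functions* (WSF)
similarity. Every function term f (typically a GO term) has significance
equal to the inverse of the number of genes annotated to it, and the edge
weight is the total significance of the functions the two genes share:

    sig(f) = 1 / |Gene(f)|
    F(i, j) = Σ_{f ∈ terms(i) ∩ terms(j)} sig(f)

Rare shared functions count for more; genes with no shared functions get
weight 0 (such edges are dropped by default).

**Propagation.** With W the column-normalized (column-stochastic) adjacency
matrix of the weighted network, P₀ the uniform distribution over the seed
genes, and restart probability r (default 0.3), the walk iterates

    P_{t+1} = (1 − r) · W · P_t + r · P₀

until the L1 change between successive iterates falls below 10⁻¹⁰.
Candidate (non-seed) genes are ranked by descending steady-state
probability.

**Validation.** Seeds are split into k = 5 equal folds; each fold is held
out in turn, re-enters the candidate pool, and its recovered ranks are
scored by top-k matched-seed counts (cutoffs 100…500), tie-aware ROC AUC,
and rank sums, over a grid of r values (0.1–0.9) with any number of
repeated, re-randomized splits. The r with the maximum total matched-seed
count is selected.

## Worked example

Everything runs from synthetic data — a planted functional module of 30
genes inside a 330-gene background:

```sh
ricewalk simulate --out-dir demo --rng-seed 7
ricewalk build --edges demo/network.txt --annotations demo/annotations.gaf --out demo/net.tsv
ricewalk rank  --network demo/net.tsv --seeds demo/seeds.txt --out demo/ranking.tsv
```

which prints

```
wrote 318 nodes / 664 edges to demo
built network: 141 nodes, 158 edges (506 zero-weight edges, policy=drop)
ranked 113 candidates in 50 iterations
```

`demo/ranking.tsv` holds the ranked candidates with their steady-state
probabilities (larger = closer to the seed set in the functional network):

```
rank	gene	score
1	b0262	0.01097601354
2	b0144	0.009135019591
3	b0202	0.009095481869
```

Cross-validate the restart parameter and reproduce the packaged
confirmation-rate table of the published top-100 ranking:

```sh
ricewalk cv --network demo/net.tsv --seeds demo/seeds.txt \
            --r-grid 0.1:0.9:0.2 --k 5 --repeats 5 --rng-seed 1 --out demo/cv.json
ricewalk report --fixture --out-prefix demo/tbl
```

The confirmation table counts top-n candidates with literature support:

```
top_n	confirmed	rate
20	11	55.00%
30	16	53.33%
40	20	50.00%
100	46	46.00%
```

Every output file gets a `.meta.json` sidecar (options, input hashes,
version) from which the run can be reproduced exactly; identical options
and seeds give byte-identical outputs.

The same operations are available as a library:

```python
from ricewalk import (GeneratorConfig, generate_network, generate_annotations,
                      build_functional_network, column_normalize,
                      make_seed_vector, rwr, rank_candidates)

cfg = GeneratorConfig(rng_seed=7)
net = generate_network(cfg)
index = generate_annotations(cfg, net.edges.nodes(), net.module_genes)
network = build_functional_network(net.edges, index)
W = column_normalize(network)
p0 = make_seed_vector(net.module_genes, W.node_order)
ranking = rank_candidates(rwr(W, p0, r=0.3).state, net.module_genes)
```

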