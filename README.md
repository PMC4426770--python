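# pnetalign

Global alignment of *uncertain* biological networks — undirected graphs whose
edges each exist independently with a stated probability. Both input networks
may be probabilistic; deterministic (all p = 1) and half-probabilistic inputs
are handled by the same code path as special cases.

The pipeline has three stages:

1. **Expected support matrix.** Node degrees of an uncertain network are random
   variables whose probability generating function (PGF) is the product of
   `(1 - p_e + p_e z)` over incident edges. Conditional degree distributions
   (given one incident edge present) come from dividing out that edge's factor.
   From these, the entrywise expectation `E(A)` of the random node-pair support
   matrix is built sparsely; isolated-node ("acnode") mass is kept as an
   implicit rank-one term applied during matrix–vector products.
2. **Similarity propagation.** The node-pair similarity vector solves
   `R = alpha * E(A) R + (1 - alpha) * S` (S = L1-normalized sequence
   similarities, uniform if absent) by power iteration with per-step L1
   renormalization (`alpha = 0.6`, `eps = 1e-6` by default).
3. **Extraction.** R is read as an m×n weight grid and a maximum-weight
   one-to-one matching of cardinality `min(m, n)` is extracted (Hungarian-style
   via `scipy.optimize.linear_sum_assignment`), with deterministic
   lexicographic tie-breaking on small instances.

Evaluation metrics: **agreement** between two alignments (Jaccard of pair
sets by default), **GOC** (mean Jaccard of GO term sets over aligned pairs),
and **GNAS** (`alpha * conserved-edge count + (1 - alpha) * summed sequence
similarity`, with `support` and `expected` conventions for uncertain edges).

Two expectation conventions are exposed via `--mode`:

- `exact` (default): topological terms are weighted by the probability that
  their enabling edges exist and the acnode probability uses
  inclusion–exclusion. This is the true possible-worlds expectation and is
  validated against a full enumeration oracle.
- `paper_literal`: omits the enabling-edge factor and uses the additive
  acnode probability (clamped at 1), for fidelity studies.

## Command line

```sh
# generate a planted instance (two networks, seqsim, annotations, manifest)
pnetalign simulate --n-nodes 20 --density 0.2 --prob-law uniform:0.3,1.0 \
    --seed 7 --out-dir inst/

# align the two networks
pnetalign align --net1 inst/net1.tsv --net2 inst/net2.tsv \
    --seqsim inst/seqsim.tsv --alpha 0.6 --eps 1e-6 --mode exact \
    --out alignment.tsv

# score the alignment
pnetalign eval --net1 inst/net1.tsv --net2 inst/net2.tsv \
    --alignment alignment.tsv --seqsim inst/seqsim.tsv \
    --annotations inst/annotations.tsv --out report.tsv

# per-node degree distributions
pnetalign dump-degrees --net inst/net1.tsv
```

File formats are plain TSV with `#` comment headers: network edge lists
(`node_a  node_b  probability`, probability optional and defaulting to 1),
sequence similarities (`node1  node2  score`), annotations (`node  term`),
alignments (`node1  node2  pair_score`). Every output file records the tool
version, the effective configuration, and MD5 checksums of its inputs, so
identical commands are byte-reproducible.

Defaults for any subcommand can be placed in a YAML file and passed with
`--config`; explicit flags override file values:

```yaml
align:
  alpha: 0.6
  eps: 1.0e-6
  mode: exact
simulate:
  n_nodes: 20
  density: 0.2
```

## Library use

```python
from pnetalign import UncertainNetwork, align, SeqSimilarity

g1 = UncertainNetwork(edges=[("a", "b", 0.4), ("a", "c", 0.9)])
g2 = UncertainNetwork(edges=[("x", "y", 0.7), ("y", "z", 0.5)])
result = align(g1, g2, SeqSimilarity({("a", "y"): 2.0}))
print(result.alignment.pairs, result.info)
```

Brute-force oracles used by the test suite (full possible-worlds enumeration
of the expected support matrix, exhaustive-injection matching) live in
`pnetalign.synthetic` alongside the seeded instance generators.
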