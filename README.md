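# sctnet

Causal gene-network reconstruction from genetical-genomics (eQTL) data
with **stochastic causal trees** (SCT) as a structure prior for Bayesian
network learning.

## The problem

In a cross of two inbred strains, each haploid segregant is genotyped at a
panel of loci and profiled for transcript abundance.  Genotype perturbs
expression, never the reverse, so genomic loci act as causal anchors
("head nodes") from which regulatory influence propagates through the
transcriptome.  The reconstruction task is to recover the directed gene
network — and, as a by-product, the transcript–locus (eQTL) linkages —
from the paired genotype/expression matrices.

`sctnet` implements:

* a **synthetic eQTL system generator**: a DAG of locus-rooted trees plus
  inter-loci and feed-forward edges, and a linear/interaction regression
  simulator for expression (`sctnet.simnet`, `sctnet.simdata`);
* the **SCT method**: trees grown stochastically from each locus, where a
  candidate child `n_c` joins parent `n_p` (grandparent `n_g`) with score

  `LLS(n_c; n_p, n_g) = c1 · log l(φ(n_g, n_c | n_p)) − log l(φ(n_p, n_c))`,

  combining a pair potential `φ(n_p, n_c) = R²` of the regression of child
  on parent (judged against per-node background sampling distributions via
  a bivariate Gaussian) and a conditional potential `φ(n_g, n_c | n_p)` —
  the R² of the first regression's residuals on the grandparent, which
  vanishes when `n_p` truly mediates (`sctnet.potentials`, `sctnet.sct`);
* the edge-frequency **prior matrix** `R[i,j] = f(i,j) / normalizer` from
  the grown trees, fed into the Gibbs structure prior
  `log P(G) = β · Σ_{(i,j) ∈ G} R[i,j]`;
* **MCMC Bayesian network structure learning** over discretized data: BDe
  scoring, top-k reciprocal candidate sets, Metropolis–Hastings over
  single-edge moves with the Hastings factor `|η(G)|/|η(G′)|`
  (`sctnet.bn`, with a compiled numba kernel for million-iteration chains);
* the **LCMS comparator**: bootstrap model selection over causal /
  reactive / independent triplet models anchored at loci (`sctnet.lcms`);
* **eQTL mapping** by depth-first reachability over sampled networks, a
  univariate t-test scan with permutation FDR (`sctnet.mapping`), and
  precision–recall / convergence-distortion / stability evaluation
  (`sctnet.evaluate`).

## Worked example

```python
from sctnet import simnet, simdata, potentials, sct

net = simnet.generate_network(simnet.NetGenConfig(
    n_transcripts=100, n_loci=5, n_extra_edges=18, rng_seed=1))
ds = simdata.simulate_dataset(net, simdata.SimParams.strong(
    n_segregants=200, rng_seed=2))
print("mean |r|, 90% interval:", simdata.correlation_summary(net, ds))

model = potentials.fit_background(ds, seed=3)
prior = sct.build_prior(ds, net.loci, model,
                        sct.SctParams(M=40, I=200, c1=5.0, p=3.0, rng_seed=4),
                        normalizer="tree_count")
true_mean = sum(prior.R.loc[u, v] for u, v in net.edges) / len(net.edges)
print("mean prior weight on true edges:", round(true_mean, 3))
print("mean prior weight overall:", round(prior.R.to_numpy().mean(), 5))
```

prints

```
mean |r|, 90% interval: (0.6772667701762349, 0.3076885924313598, 0.8875268560797119)
mean prior weight on true edges: 0.179
mean prior weight overall: 0.00363
```

— the simulator reproduces the strong-regime correlation structure (mean
parent–child |r| ≈ 0.68 with the central 90% interval roughly 0.31–0.89),
and the SCT prior concentrates about fifty times more mass on true edges
than on arbitrary pairs.
Feeding `prior` into `sctnet.bn.mcmc_run` with `beta=16` augments
structure learning; `sctnet.pipeline.run_experiment` wires the whole
study (simulate → prior → learn → evaluate → map) and persists every
artifact with a manifest.  A `sctnet` command-line tool exposes the same
stages (`sctnet simulate-network`, `simulate-data`, `build-prior`,
`learn`, `map`, `run-all`).

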