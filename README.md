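# microbiont

Phylogenetic analysis of host–gut-microbiome association for multi-species
amplicon surveys: does a host lineage's bacterial repertoire evolve along
the host phylogeny, and do hosts gain bacteria more easily when those
bacteria are close relatives of ones they already carry?

The package was built for the study design of a six-species leaf-beetle
(*Galerucella*) gut-microbiome survey — several host species sampled at
multiple sites, 16S ASV count tables, a dated host phylogeny spanning
0.077–4 Myr of divergence, and a character tree for the dominant ASVs — but
every stage works on any comparable inputs (dated host tree, ASV table with
species/site metadata, ASV tree).

## The model

Each host lineage carries a **repertoire** `R(t)`, the set of ASVs it hosts
at time `t`. Along each branch of the dated host tree the repertoire
evolves as a continuous-time Markov process:

* a present ASV is lost at rate `λ_loss`;
* an absent ASV `j` is gained at rate `λ_gain · η(j, R)`, with

  `η(j, R) = ( d̄ / d(j, R) )^β`

  where `d(j, R)` is the mean patristic distance on the ASV tree from `j`
  to the members of `R`, `d̄` the mean pairwise ASV distance, and `β ≥ 0`
  the phylogenetic-distance effect (`β = 0`, or an empty repertoire, makes
  the process neutral);
* both daughters of a host split inherit the parental repertoire;
* the root repertoire is i.i.d. Bernoulli(π) per ASV.

Inference is Bayesian with data augmentation: an MCMC samples
`(λ_gain, λ_loss, β)` jointly with complete gain/loss histories
(time-stamped events on every branch plus ancestral node repertoires),
conditioned on the observed presence/absence of the per-species
most-abundant ASVs. Priors are `λ ~ Exp(10)` and `β ~ Exp(1)`. Support for
the distance effect is measured by the Savage–Dickey Bayes factor
`BF = p(β=0) / p(β=0 | data)` (prior over posterior density at the point
null), read on the usual evidence bands (≥10 strong, ≥100 decisive).
Posterior interaction probabilities at internal nodes and at dated time
slices yield ancestral bipartite host×ASV networks (edges kept at posterior
probability ≥ 0.70, weighted by that probability; node-level ancestral
states at > 0.60), whose structure is summarized by weighted bipartite
modularity (Barber's Q, maximized by multi-restart label propagation) with
module identities matched through time.

Supporting statistics: per-species top-k ASV selection and its read
coverage, sharing fractions, Shannon and ACE α-diversity, Bray–Curtis
dissimilarity, and PERMANOVA (global and pairwise, Benjamini–Hochberg) for
site effects.

A synthetic-study generator reproduces the whole design with known ground
truth (dated six-species host tree, 45-ASV Yule tree, repertoires evolved
under known parameters, per-site count tables with a 2000-ASV rare tail),
so the entire pipeline is testable end to end without any data download.

## Worked example

```python
import warnings
from microbiont.model import ChainConfig, HostRepertoireModel
from microbiont.simulate import simulate_study
from microbiont.tables import InteractionMatrix, top_k_per_species, coverage_fraction
from microbiont.trees import parse_newick, patristic_distances

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table, history, truth, manifest = simulate_study(seed=1)
    table = table.drop_excluded_taxa()
    selections, matrix = top_k_per_species(table, k=10)
    _, coverage = coverage_fraction(table, {a for s in selections.values() for a in s})
print(f"union of per-species top-10: {len(matrix.asvs)} ASVs, mean coverage {coverage:.2f}")

host = parse_newick(manifest["host_tree_newick"])
asv_tree = parse_newick(manifest["asv_tree_newick"])
keep = [a for a in matrix.asvs if a in set(asv_tree.tip_labels)]
tips = InteractionMatrix(hosts=matrix.hosts, asvs=keep,
                         values=matrix.to_frame()[keep].to_numpy())
model = HostRepertoireModel(tips, host, patristic_distances(asv_tree))
result = model.fit(ChainConfig(cycles=20_000, thinning=100, chains=3, seed=1),
                   record_ages=[2.0, 1.0, 0.0])
print(result.summary().round(3))
bf = result.savage_dickey_bf()
print(f"Savage-Dickey BF (beta != 0): {bf['bf']:.1f} [{bf['category']}]")
rates = result.event_rate_summary("root_age")
print(f"posterior mean events/Myr (root-age basis): {rates.total_per_myr:.1f} "
      f"({rates.gains_per_myr:.1f} gains, {rates.losses_per_myr:.1f} losses)")
```

prints

```
union of per-species top-10: 31 ASVs, mean coverage 0.68
              mean     sd  ci2.5  ci97.5  fixed   psrf
parameter
lambda_gain  0.210  0.059  0.119   0.358  False  1.012
lambda_loss  0.399  0.106  0.218   0.626  False  1.003
beta         0.785  0.730  0.028   2.788  False  1.001
Savage-Dickey BF (beta != 0): 0.9 [no effect]
posterior mean events/Myr (root-age basis): 28.5 (14.2 gains, 14.4 losses)
```

Reading the output: the six species' top-10 selections overlap into a
31-ASV union that captures 68% of reads per sample; the fitted gain and
loss rates imply roughly 28 gain/loss events per Myr of elapsed time across
the modeled repertoires, split about equally; PSRF ≈ 1 says the three
chains agree. On this particular synthetic draw (generated at a moderate
β = 1.5) the Bayes factor finds no resolvable distance effect — with only
six host tips, presence/absence data identify β weakly (see
`docs/methods.md`).

`result.interaction_probabilities(age=1.0)` returns the posterior
host-lineage × ASV probability matrix one Myr before the present, ready for
`microbiont.networks.build_ancestral_network` and
`microbiont.modularity.dirt_lpawb_plus`.

The same workflow runs from the shell:

```bash
microbiont simulate --seed 1 --outdir study/
microbiont all --seed 1 --outdir run/        # full pipeline -> run/report.json
microbiont tree-info study/host_tree.nwk
```

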