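# Methods

## The host-repertoire gain/loss process

The unit of state is the repertoire `R(t)` of a host lineage: the subset of
a fixed pool of M ASVs it hosts at time `t` (Myr). On every branch of a
dated, ultrametric host phylogeny the repertoire follows a continuous-time
Markov chain over the 2^M subsets in which exactly one ASV flips at a time:

* loss of a present ASV at rate `λ_loss` (events/Myr/ASV);
* gain of an absent ASV `j` at rate `λ_gain · η(j, R)`, with
  `η(j, R) = (d̄ / d(j, R))^β`, where `d(j, R)` aggregates (mean by
  default, minimum optionally) the patristic distances on the ASV character
  tree from `j` to the current members of `R`, and `d̄` is the mean
  off-diagonal ASV distance.

The modifier is dimensionless and scale-invariant (rescaling all ASV branch
lengths cancels), equals 1 when `β = 0` or `R = ∅`, and rises when the
candidate is closer than average to the current repertoire. Empty
repertoires are legal: nothing forces a host to carry bacteria. At a host
split both daughters copy the parental repertoire; the root repertoire is
product-Bernoulli(π). π is either a fixed number or, by default, the
stationary occupancy `λ_gain/(λ_gain+λ_loss)` of the neutral single-ASV
chain tracked at the current parameter values (this choice is closed under
the `β = 0` factorization of the process into independent two-state
chains). Assumptions worth stating: ASVs are a closed pool (no
speciation/extinction of symbionts), rates are homogeneous across branches
and ASVs, and the ASV tree is known without error.

Two exact oracles accompany the generative simulator (an event-by-event
Gillespie walk down the tree):

* `exact_tip_likelihood` builds the dense 2^M generator and prunes with
  per-branch matrix exponentials (refused above M = 14);
* `independent_pruning_loglik` handles `β = 0`, where the ASVs decouple
  into M two-state chains (Felsenstein pruning each).

Simulator, augmented-history density and oracles share one rate
implementation; their mutual agreement is enforced in the test suite by a
χ² goodness-of-fit of 50,000 simulated histories against the exact joint
tip-pattern distribution, and by the `β = 0` factorization identity at
relative error < 1e-10.

## Data-augmented MCMC

The posterior is sampled over `(λ_gain, λ_loss, β)` *plus* the complete
history: per-branch event lists and ancestral node repertoires, with tip
repertoires clamped to the data. Given the history, the log density is
linear in the rates,

    ld = −λ_gain·G − λ_loss·P + n_gain·log λ_gain + n_loss·log λ_loss + E,

with `G` the integrated distance-modified gain propensity, `P` the
integrated repertoire size and `E` the summed log modifiers at the gain
events; these per-branch sufficient statistics are cached, so rate updates
cost O(1). Moves, all Metropolis–Hastings against the exact augmented
density (numba kernels; the readable Python implementations are the test
oracles):

* multiplicative scaling on each free rate (Hastings ratio λ'/λ);
* on β, a multiplicative scaling and a reflected-at-zero Gaussian walk on
  alternating cycles — the walk mixes across the `β ≈ 0` boundary that the
  Savage–Dickey estimate depends on;
* single branch×ASV path redraws: an endpoint-conditioned bridge of the
  *neutral* two-state chain proposed by uniformization. For rates (g, l)
  the uniformized jump chain at rate g+l has both rows equal to
  (l/(g+l), g/(g+l)), so the number of virtual jumps has a closed-form
  conditional and intermediate states are i.i.d. — bridge sampling is exact
  and cheap. Acceptance weighs the full repertoire-coupled density against
  the neutral proposal density;
* whole-branch sweeps: fresh bridges for every ASV on one branch accepted
  jointly — one density evaluation refreshes M paths (the workhorse move;
  on the study-sized problem it updates every branch×ASV pair per cycle);
* node flips: toggle one ASV at an internal node (root included) and
  redraw that ASV's paths on all incident branches; the endpoint-dependent
  bridge normalizers enter the Hastings ratio, and the root prior term
  enters for root flips.

Defaults: one sweep per branch per cycle, single-pair redraws on 2% and
node flips on 5% of the respective move spaces per cycle (floors of 4 for
tiny problems), scale step 0.4, β walk step 0.5, per-branch event capacity
4096 (a proposal overflowing the capacity is rejected; never observed in
practice). Initialization: majority-rule upward pass for node states, then
neutral bridges. Chains are seeded through `numpy.random.SeedSequence`
spawns, so runs are byte-reproducible.

Correctness was established against exact references rather than plausibility:
the kernel density equals the Python history density to 1e-9 on random
histories; node-state marginals at fixed parameters match brute-force CTMC
enumeration; the marginal posterior of a free rate (and of β on two-tip
instances) matches fine-grid posteriors computed from
`exact_tip_likelihood`; prior-sampling mode (likelihood off) reproduces the
priors by KS test. One practical-mixing caveat: the β posterior is
right-skewed with a heavy upper tail, and a single finite chain's *mean*
is itself right-skewed across seeds (rare long tail excursions carry the
mass), so chain means scatter a few percent below/above the exact mean
even when pooled CDFs and quantiles match the grid closely. Interval
summaries and the Savage–Dickey density at 0 are unaffected.

### Priors, diagnostics, Bayes factor

`λ ~ Exponential(10)` (mean 0.1/Myr/ASV — weakly informative on the scale
implied by repertoires turning over a few times across a ~4-Myr tree) and
`β ~ Exponential(1)`, whose density at 0 is exactly 1, keeping the
Savage–Dickey numerator closed-form. Convergence uses the Gelman–Rubin
PSRF on post-burn-in samples of ≥ 2 chains; the pipeline warns (not
aborts) above 1.1. The posterior density at `β = 0` is estimated one-sided:
the fraction of samples in `[0, ε)` divided by ε, with ε from a
Silverman-type rule `0.9·min(sd, IQR/1.34)·n^(−1/5)` and reported. When no
sample falls below ε the BF is reported as the lower bound `ε·(n+1)` and
flagged. Default chain protocol: 3 chains × 150,000 cycles, thinning 500,
10% burn-in; every test and the acceptance script use scaled-down chains
(stated below).

### Event rates

Posterior mean gain/loss event counts are normalized either by total tree
length (events per lineage-Myr; default) or by root age (events per Myr of
elapsed time, summed over contemporaneous lineages). Both are reported:
with ~45 ASVs at the default rates the root-age basis gives ~22–28 total
events/Myr on the preset tree, the tree-length basis ~7.

## Ancestral networks and modularity

Lineages crossing age `t` are found by the half-open rule
`age(child) < t ≤ age(parent)` (a split dated exactly `t` has happened at
`t`; `t = 0` returns the tips), so lineages are never double-counted and
the preset tree yields 4/5/6 lineages at 2/1/0 Ma. Posterior interaction
probabilities are the per-sample frequencies of ASV presence in the
recorded lineage repertoires. Network edges keep probability ≥ 0.70
(inclusive) with the probability as weight; node-level ancestral states
use strictly > 0.60; both thresholds are configurable and deliberately
separate knobs.

Barber's bipartite modularity `Q = (1/m) Σ_ij (A_ij − k_i d_j/m) δ(g_i,h_j)`
is maximized by weighted label propagation: columns and rows alternately
adopt the module with the largest own contribution (ties to the lowest
label; all-negative contributions leave a node in its own module), which
ascends Q monotonically to a local maximum; a multi-restart wrapper adds
seeded random initializations and forced module counts 2..min(rows, cols)
and keeps the best Q. An exhaustive oracle (row set-partitions × per-column
optimal assignment — exact because column choices are independent given the
row partition) verifies global optimality on every 4×4 battery network.
Modules are numbered by descending total weight; across time points, module
identities are matched by maximum-total-Jaccard assignment
(`linear_sum_assignment`) of row memberships after expanding ancestral
lineages to their extant descendants, ties to the lower present-day id,
unmatched modules relabeled fresh.

## Community statistics

Shannon diversity is reported in nats. ACE uses the classic
frequency-count estimator with rare cutoff 10; when the rare-class coverage
is zero (all rare taxa singletons) it falls back to bias-corrected Chao1
and flags the value. Bray–Curtis is the usual ratio of summed absolute
differences. PERMANOVA computes the pseudo-F from the squared-distance SS
partition and permutes labels with an add-one p-value
`(#{F* ≥ F}+1)/(n_perm+1)`; the identity permutation enters once as the
observed statistic. Pairwise tests run on pair submatrices with
Benjamini–Hochberg adjustment (`scipy.stats.false_discovery_control`).
Two corner cases verified by enumeration: with all off-diagonal
distances equal the partition gives F = 1 exactly (not 0), and two
perfectly separated groups of three have an exhaustive permutation p of
0.1, which the Monte-Carlo p reproduces. The site tests default to 999
unstratified permutations, run within each host species where ≥ 2 sites
have ≥ 2 samples.

## The synthetic study generator

`simulate_study` emulates the survey design end to end with known truth:

| parameter | default | rationale |
|---|---|---|
| host tree | 6 species; splits 0.077, 1.0, 2.2, 2.5 Ma; root 4.0 Ma | the dated splits the analysis slices at 2/1/0 Ma presuppose |
| sampling | 6 species × 1–3 sites × 3–9 individuals = 85 samples | multi-site, unbalanced design of the survey |
| ASV pool | 45 dominant ASVs on a unit-height Yule tree + 2000 background ASVs | dominant union ≈ 45; total richness ≈ 2000 |
| `λ_gain`, `λ_loss` | 0.1, 0.35 /Myr/ASV | stationary occupancy 10/45 ≈ the 10 dominant ASVs per species; gain and loss event flows balance; ~22–24 events/Myr (root-age basis) on the preset tree |
| `β` | 1.5 | a moderate phylogenetic-distance effect (see power note) |
| π | 10/45 | stationary occupancy of the neutral chain |
| depth | lognormal, median 50k reads, sdlog 0.4 | typical 16S library sizes |
| dominant abundances | lognormal sdlog 1.0 per species×ASV | skewed within-repertoire abundances |
| site effect | lognormal sdlog 0.8 per site×ASV | makes PERMANOVA site structure detectable |
| background tail | rank^(−0.8) means carrying 30% of reads | leaves the dominant pool ~70% of reads per sample; no background ASV rivals a dominant one |
| excluded taxa | 12 mitochondrial/chloroplast/unassigned ASVs | exercises the load-time filter |

The generator reproduces the *shape* of real amplicon data, not its full
messiness: no chimeras, no index hopping, no compositional (relative-
abundance) biases from PCR or copy number, no read-level errors, and
contamination off by default (a low-rate flag exists for robustness
checks). Passing tests therefore demonstrate correctness of the algorithms
under the stated generative model, not robustness to those artifacts.

### Power of the distance-effect test

With six host tips, presence/absence data identify β weakly: shared
ancestry already explains most co-occurrence, so the marginal likelihood
moves little unless the effect is large. A power sweep at the study design
(40-ASV pools, seeds fixed in advance, 10 datasets per effect size) gave
Savage–Dickey BF > 10 in 2/10 datasets at β = 2, 3/10 at β = 3, 6/10 at
β = 4 and 8/10 at β = 5; chains initialized at the generating β fall back
to the same posterior, and null data calibrate correctly (median BF ≈ 0.9),
so this is a property of the design, not of the sampler. The calibration
battery therefore uses β = 5 as its strong-effect regime, and on typical
draws at the default β = 1.5 the reported BF lands in the weak/positive
band. Real data can of course be more informative than the generator (more
structured ASV trees, stronger within-module contrast).

## Numerical choices and conventions

* Ages run backward from the present; ultrametricity tolerance 1e-9 Myr.
* Distances in η are floored at 1e-12 to avoid division by zero for
  identically placed ASVs.
* Abundance ranking ties break lexicographically by ASV id; top-k ranking
  pools sites (a per-sample-mean option exists).
* Mitochondrial, chloroplast and taxonomically unassigned ASVs are dropped
  at load time.
* Selected ASVs absent from the ASV character tree are excluded from the
  model (with a warning) — the repertoire model needs distances.
* Threshold comparisons: network edges ≥ 0.70, node ancestral states
  > 0.60 (strict), both configurable.
* The pipeline report contains no timestamps and rounds floats to 10
  decimals, so a rerun at the same seed is byte-identical.

## Problem sizes used by the test and acceptance batteries

Simulator GOF: 4 tips × 3 ASVs × 50,000 histories. Grid-posterior checks:
2 tips × 1 ASV at 50,000 cycles (total variation < 0.05). Parameter
recovery: 20 datasets, 6-tip preset tree × 40 ASVs, single chains of
20,000 cycles (thin 100). BF calibration: 10 null + 10 strong datasets,
10,000-cycle chains. PERMANOVA calibration: 1000 null datasets, n = 24,
199 permutations. The acceptance script runs the full pipeline with
3 × 30,000-cycle chains; the full-length protocol (3 × 150,000, thin 500)
is the library default.

## Known limitations

* The three-state elaboration of host-repertoire models (a distinct
  "potential host" class) is out of scope; states are present/absent.
* Rates are homogeneous in time and across lineages; no host-tree
  uncertainty; a single host tree per run.
* The exact joint oracle is capped at 14 ASVs (2^M states); beyond that
  only the `β = 0` factorization and simulation-based checks apply.
* β's posterior upper tail mixes slowly at small data sizes (see above);
  report interval summaries, not single-chain means, when β is weakly
  identified.
* NMDS ordination, rarefaction and plotting are intentionally absent;
  Bray–Curtis matrices are exported for external ordination tools.
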