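# Methods

## The model-selection problem

Bayesian admixture clustering assigns `N` diploid individuals, genotyped at
`L` unlinked loci, soft memberships in `K` latent clusters. The likelihood
of the data is non-decreasing in `K`, so `K` itself cannot be chosen by
fit alone. `popkdic` implements the Deviance Information Criterion in its
mixture-stabilized form as the selection rule, together with the sampler
that produces the posterior draws it needs, three competing estimators of
`K`, and a coalescent simulation harness for measuring selection accuracy.

## The admixture model with inbreeding

Parameters: cluster allele frequencies `P[k, l, ·]` (Dirichlet(λ) prior,
λ = 1), individual admixture proportions `Q[i, ·]` (symmetric
Dirichlet(α), with α given a Uniform(0, 10] hyperprior), and, in
inbreeding mode, a per-cluster inbreeding coefficient `f_k` (Uniform(0, 1)
prior). Each allele copy carries a latent cluster of origin drawn from
`Q[i]`. Conditional on an ordered origin pair `(k1, k2)` at a locus:

* distinct origins — the two copies are independent draws from their
  clusters' frequency vectors;
* shared origin `k` — the pair is autozygous with probability `f_k`:
  homozygotes have probability `f_k p + (1 − f_k) p²`, heterozygotes
  `(1 − f_k)·2·p_a p_b`.

The inbreeding coefficient comes in two granularities. The default is one
`f_k` per cluster — the excess homozygosity of that cluster. Under
partial selfing, however, individuals within one population differ
strongly in autozygosity (an individual with `g` consecutive selfing
generations is autozygous at a fraction `1 − 2^−g` of its loci, and `g`
varies): this identity disequilibrium cannot be absorbed by any single
per-cluster coefficient, and the misfit is large enough that splitting a
selfed deme into high-/low-autozygosity subclusters genuinely raises the
likelihood, biasing cluster-number selection upward. The
`"individual"` granularity therefore fits one `f_i` per individual
(Uniform(0,1) prior, Metropolis update), which is the minimal analogue of
modeling each individual's selfing history explicitly; benchmarks use it
whenever the data-generating model includes selfing.

The Gibbs sweep redraws every origin pair from its exact conditional over
all `K²` ordered cells (necessary because `f` couples the two copies when
origins coincide — independent per-copy updates would be wrong for
`f > 0`), then redraws `P` and `Q` from their conjugate Dirichlet
conditionals, then takes one random-walk Metropolis step on `α` (proposal
sd 0.05) and one per inbreeding coefficient (proposal sd 0.1). Missing
allele copies are marginalized out of the likelihood and never imputed
into the Dirichlet counts. Initialization: uniform `Q`, `P` from the
prior, `f = 0.01`, `α = 1`.

Two deliberate simplifications, both flagged:

* For an autozygous same-cluster homozygote both copies are counted in
  `P`'s Dirichlet update even though only one founder copy exists; the
  stationary distribution of `P` under `f > 0` is therefore approximate.
* The genotype model for distinct ordered origins is symmetrized over
  which copy came from which cluster (allele copy order carries no
  meaning); the constant heterozygote multiplicity is applied once at
  likelihood-recording time, where it shifts the deviance identically for
  every `K` and cannot affect selection.

## DIC for mixtures

Writing `f_i(θ)` for the probability of individual `i`'s genotype with the
origins marginalized out (`θ = (P, Q, α, f)`), the deviance is
`D(θ) = −2 Σ_i log f_i(θ)`. Over `T` retained draws:

    Dbar = −2 Σ_i mean_t log f_i(θ_t)          (posterior mean deviance)
    Dhat = −2 Σ_i log( mean_t f_i(θ_t) )       (stabilized plug-in)
    pD   = Dbar − Dhat,   DIC = Dbar + pD = 2 Dbar − Dhat

Because `f_i` is invariant under permutation of cluster labels, this
estimator is immune to label switching; Jensen's inequality makes
`pD ≥ 0`. The classic plug-in variant (deviance at a posterior point
estimate) is provided for comparison only; it requires consistent
relabeling and is excluded from benchmarks. Per-individual likelihoods
underflow double precision near 100 loci, so both accumulators are
maintained streaming in log space (running-max log-sum-exp); raw
probabilities are never summed anywhere.

`K` is selected by minimizing DIC, taking the minimum across independent
chains within each `K` first: the likelihood surface is multimodal for
larger `K` and chains land in different modes, so the best fit any chain
found is the robust per-`K` summary. Exact ties break toward smaller `K`.

## Comparator estimators

* **ln P(X|K)** — mean retained total log-likelihood minus half its sample
  variance; maximized over the across-chain mean.
* **Evanno ΔK** — across-chain mean absolute second difference of L(K)
  divided by the across-chain sd of L(K); only defined at interior grid
  points, so `K = 1` is never selectable.
* **Tracy–Widom eigenanalysis** — columns of allele dosage are centered
  and scaled by the binomial sd `√(p(1−p))`; eigenvalues of the
  individual×individual covariance are tested largest-first against TW1
  with a moment-based effective-marker correction
  `n_eff = (m+1)(Σλ)² / ((m−1)Σλ² − (Σλ)²)`; the estimate is 1 plus the
  number of rejections. TW1 critical values are embedded as a static
  upper-tail table (0.4501, 0.9793, 1.4538, 2.0234, 2.4224, 3.2724 at
  levels 0.10…0.001) with log-linear interpolation between; default
  significance levels 0.05, 0.01, 0.001. Multi-allelic loci are expanded
  to one dosage column per allele; monomorphic columns are dropped.

These comparators consume this package's own sampler output. Benchmark
tables therefore compare the *statistics*, not the external programs that
popularized them; in particular the correlated-allele-frequency ("F")
model is not implemented, so configurations where that model is what
rescues a statistic are outside scope.

## Coalescent simulator

Time is scaled in units of 4N generations, so a within-deme lineage pair
coalesces at rate 2; the migration parameter `M = 4Nm` is the scaled rate
at which a lineage moves to each specific other deme. This parameterization
was validated two ways: pairwise coalescence times agree with an
independent simulator (msprime) under identical demographies, and the
equilibrium two-deme prediction FST ≈ 1/(1 + 2M) matches the simulated
strong-migration value (M = 10 → 0.048).

Scenarios: star split of `K` demes at τ (default 0.5); caterpillar tree
with successive splits spaced 0.5 apart (the two most recently diverged
demes split at 0.5); island migration between all deme pairs after a star
split; and a star split with partial self-fertilization. Each locus is an
independent genealogy carrying exactly one mutation placed uniformly on
total branch length (fixed-segregating-site scheme), which guarantees
every locus is diallelic and polymorphic in the sample. Haplotypes are
paired into diploids in sampled order (exchangeable under the coalescent).
Selfing draws per-individual generation counts `g ~ Geometric(1 − s)`
(capped at 10) and makes each locus autozygous independently with
probability `1 − 2^−g`, giving mean autozygosity `s/(2 − s)`. Selfing
rates for the inbred scenario are drawn Uniform(0, 0.99) per deme per
dataset (the distribution is configurable; nothing downstream is
sensitive to its exact form, only to the presence of strong
heterozygote deficits).

FST is Hudson's ratio-of-sums estimator per deme pair (per-locus
numerator `(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`, denominator
`p1(1−p2)+p2(1−p1)`, summed over loci before dividing), averaged over
pairs; negative per-locus values are retained.

What the simulator does not emulate: recombination within loci,
microsatellite (stepwise) mutation, population growth or bottlenecks,
SNP ascertainment beyond the single-site scheme, genotyping error.
Passing benchmarks therefore demonstrate behavior under idealized
unlinked biallelic markers with known truth, not robustness to the
artefacts of real panels.

## Benchmark harness and problem sizes

A scenario is simulated data → multi-chain fits over a `K` grid → one
selected `K` per criterion → accuracy = fraction of replicates recovering
the simulated `K`. Seeds are derived arithmetically (replicate seed =
base + index; chain seed = replicate seed × 1000 + chain index) so every
number in a table is exactly reproducible. Invalid replicates (aborted
chains) are excluded from the denominator and reported, never silently
dropped.

The full-scale study design (50 replicates × 5 chains × 500,000 burn-in,
50,000 retained draws, six `K` values) is preserved as configuration but
is cluster-sized. Package defaults use a scaled-down profile (10
replicates, 3 chains, 20,000 burn-in, 2,000 retained, thinning 10). The
shipped test suite scales further so the whole suite runs on one CPU in
minutes: data-generating conditions are kept at full size (50 diploids
per deme, 100 loci, τ = 0.5), while the accuracy tests use 2 chains, a
5,000 burn-in / 1,500 retained / thinning 5 schedule, 3 replicates per
strong-structure scenario (Split K=3, Inbred K=2, M_2.0 K=2 — checked
pooled, since per-cell binomial noise at n = 3 exceeds a useful band),
8 replicates of the 10-locus robustness cell and 2 of the short-split
cell. By default the sampler runs in inbreeding mode only for selfing
data (at individual granularity there): on outbred data the `f`
coefficients are unidentified, and their posterior noise is large
relative to the DIC gap between the true `K` and `K + 1`.

When the candidate `K` exceeds the true value, the surplus cluster
empties and `DIC(K+1) − DIC(K)` is a small positive effective-parameter
penalty that grows with sample size. Reliability of the minimum-DIC rule
is this gap divided by the Monte Carlo noise of `Dbar`, which shrinks
with retained draws — at full scale (50,000 retained) the rule is
near-deterministic; at reduced schedules occasional spurious `K + 1`
selections are expected small-sample behavior of a min-over-chains rule,
not a property of DIC, and at very small N (a few dozen individuals) the
`K` vs `K + 1` comparison is a coin flip at any affordable chain length.

## Numerical and design choices

* Allele recoding: observed raw labels map to dense codes in ascending
  numeric order per locus; deterministic and order-invariant.
* STRUCTURE dialects: one row per individual (two columns per locus) by
  default, two-rows-per-individual behind a flag; missing sentinel −9,
  configurable; ploidy other than 2 rejected.
* The chain accumulates posterior means of `Q`, `P`, `f` with greedy
  per-draw relabeling against the running mean (Hungarian assignment on
  squared `Q` distance); DIC accumulators need no relabeling by
  construction.
* Assignment accuracy between posterior-mean `Q` and truth is computed
  maximizing over cluster-to-deme assignments, since labels are
  arbitrary.
* Degenerate inputs: loci with zero non-missing calls are rejected;
  monomorphic loci are carried by the sampler (`J = 1`) but dropped from
  eigenanalysis; a deme with fewer than two sampled allele copies
  everywhere is an FST error.
* The Evanno statistic requires ≥ 2 chains, ≥ 3 consecutive grid points
  and nonzero across-chain sd; violations raise rather than return
  silently wrong values.

## Known limitations

* The sampler implements the uncorrelated allele-frequency model only;
  under very weak differentiation (strong migration, τ ≪ 0.5) accuracy
  degrades exactly as the benchmarks show.
* The inbreeding coefficients (per cluster or per individual) are
  simplifications of a full selfing-rate model: they capture the
  heterozygote deficit and, at individual granularity, identity
  disequilibrium, but are not a generative match to the selfing
  simulator (no explicit selfing-generation structure).
* Plug-in DIC is only meaningful after relabeling and is excluded from
  benchmarks by default.
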