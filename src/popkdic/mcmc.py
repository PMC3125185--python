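"""Gibbs sampler for the Bayesian admixture clustering model.

The model is the classic admixture model for multilocus genotypes: each
individual ``i`` has a vector ``Q_i`` of membership proportions over ``K``
clusters (Dirichlet(alpha) prior), each cluster ``k`` has allele-frequency
vectors ``P_{k,l}`` per locus (flat Dirichlet(lambda) prior), and each
allele copy draws a latent cluster of origin from ``Q_i``. In inbreeding
mode a per-cluster coefficient ``f_k`` inflates homozygosity whenever both
copies at a locus originate from the same cluster:

    P(aa | k, k) = f_k p + (1 - f_k) p^2
    P(ab | k, k) = (1 - f_k) 2 p_a p_b          (a != b)

The chain's deliverable is not the parameter trace but per-individual
likelihood accumulators over retained draws — the raw material of DIC.
Accumulation is streaming and in log space: at 100+ loci per-individual
likelihoods underflow double precision, so raw probabilities are never
summed directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import _kernels
from .genotypes import GenotypeTable


@dataclass
class ChainConfig:
    """MCMC schedule and priors for one chain.

    Defaults follow the protocol used for the benchmark study at full
    scale: 500,000 burn-in sweeps, then 50,000 retained draws with a
    thinning interval of 10 sweeps. Test and scaled-down benchmark
    profiles pass smaller values.
    """

    K: int = 1
    burn_in: int = 500_000
    retained: int = 50_000
    thinning: int = 10
    seed: int = 0
    inbreeding_mode: bool = False
    #: "cluster": one coefficient f_k per cluster (excess homozygosity of
    #: that cluster). "individual": one f_i per individual, capturing
    #: identity disequilibrium (variation in autozygosity between
    #: individuals, as under partial selfing).
    inbreeding_granularity: str = "cluster"
    lam: float = 1.0  # Dirichlet prior on allele frequencies
    alpha_max: float = 10.0  # Uniform(0, alpha_max] prior on alpha
    alpha_proposal_sd: float = 0.05
    f_proposal_sd: float = 0.1
    relabel: bool = True  # greedy relabeling of posterior-mean accumulators

    def __post_init__(self) -> None:
        if min(self.K, self.retained, self.thinning) < 1 or self.burn_in < 0:
            raise ValueError("K, retained, thinning must be >= 1; burn_in >= 0")
        if self.inbreeding_granularity not in ("cluster", "individual"):
            raise ValueError("inbreeding_granularity: 'cluster' or 'individual'")

    @property
    def f_by_individual(self) -> bool:
        return self.inbreeding_granularity == "individual"


@dataclass
class ModelState:
    """Snapshot of sampler parameters (used for plug-in deviance)."""

    P: np.ndarray  # K x L x Jmax
    Q: np.ndarray  # N x K
    alpha: float
    f: np.ndarray  # K (per cluster) or N (per individual)
    f_by_individual: bool = False
    Z: np.ndarray | None = None  # N x L x 2


@dataclass
class ChainDraws:
    """Streaming accumulators over retained draws of one chain.

    ``loglik_sum[i]`` is the sum over retained draws of the per-individual
    log-likelihood; ``lik_logsumexp[i]`` is ``log sum_t f_i(theta_t)``
    accumulated in log space. Jensen's inequality guarantees
    ``lik_logsumexp / T >= exp(mean log)``, i.e. a non-negative effective
    parameter count downstream.
    """

    K: int
    T: int
    loglik_sum: np.ndarray
    lik_logsumexp: np.ndarray
    posterior_mean_Q: np.ndarray
    posterior_mean_f: np.ndarray
    trace: np.ndarray
    posterior_mean_P: np.ndarray | None = None
    posterior_mean_alpha: float = np.nan
    f_by_individual: bool = False
    seed: int | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.loglik_sum)

    def mean_state(self) -> ModelState:
        """Posterior-mean parameter point (relabeled if the chain was)."""
        if self.posterior_mean_P is None:
            raise ValueError("chain did not accumulate posterior-mean P")
        return ModelState(
            P=self.posterior_mean_P,
            Q=self.posterior_mean_Q,
            alpha=self.posterior_mean_alpha,
            f=self.posterior_mean_f,
            f_by_individual=self.f_by_individual,
        )


def genotype_prob(
    a: int,
    b: int,
    k1: int,
    k2: int,
    P: np.ndarray,
    f: np.ndarray,
    locus: int = 0,
) -> float:
    """Probability of the unordered genotype {a, b} given origin pair.

    Same-cluster origins use the inbreeding genotype frequencies; distinct
    origins symmetrize over which copy came from which cluster. Missing
    copies (negative codes) are marginalized (factor 1 each).
    """
    if a < 0 and b < 0:
        return 1.0
    if a < 0 or b < 0:
        obs = b if a < 0 else a
        k = k2 if a < 0 else k1
        return float(P[k, locus, obs])
    if k1 == k2:
        pa = P[k1, locus, a]
        if a == b:
            return float(f[k1] * pa + (1 - f[k1]) * pa * pa)
        return float((1 - f[k1]) * 2 * pa * P[k1, locus, b])
    if a == b:
        return float(P[k1, locus, a] * P[k2, locus, b])
    return float(P[k1, locus, a] * P[k2, locus, b] + P[k1, locus, b] * P[k2, locus, a])


def genotype_loglik(a, b, k1, k2, P, f, locus: int = 0) -> float:
    """Log of :func:`genotype_prob`; ``-inf`` for zero-probability cells."""
    p = genotype_prob(a, b, k1, k2, P, f, locus)
    return float(np.log(p)) if p > 0 else -np.inf


def _het_log2(table: GenotypeTable) -> np.ndarray:
    """Per-(i, l) log-multiplicity turning ordered pairs into genotypes."""
    a = table.alleles
    het = (a[:, :, 0] >= 0) & (a[:, :, 1] >= 0) & (a[:, :, 0] != a[:, :, 1])
    return np.where(het, np.log(2.0), 0.0)


def _init_state(table: GenotypeTable, cfg: ChainConfig, rng) -> tuple:
    n, l = table.n_individuals, table.n_loci
    k = cfg.K
    jmax = table.max_alleles
    J = table.locus_allele_counts.astype(np.int64)
    P = np.zeros((k, l, jmax))
    for j in range(l):
        g = rng.standard_gamma(cfg.lam, size=(k, J[j]))
        P[:, j, : J[j]] = g / g.sum(axis=1, keepdims=True)
    Q = np.full((n, k), 1.0 / k)
    Z = np.zeros((n, l, 2), dtype=np.int8)
    nf = n if cfg.f_by_individual else k
    f = np.full(nf, 0.01 if cfg.inbreeding_mode else 0.0)
    return J, P, Q, Z, f


def _match_labels(Q: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Permutation of clusters minimizing squared distance to ``ref``."""
    cost = ((Q[:, :, None] - ref[:, None, :]) ** 2).sum(axis=0)
    src, dst = linear_sum_assignment(cost)
    order = np.empty(len(src), dtype=int)
    order[dst] = src  # order[k] = chain cluster matched to reference slot k
    return order


def run_chain(table: GenotypeTable, config: ChainConfig) -> ChainDraws:
    """Run one seeded chain and return its DIC accumulators.

    Executes ``burn_in`` sweeps, then ``retained * thinning`` sweeps,
    recording at every ``thinning``-th sweep the origin-marginalized
    per-individual likelihood f_i(theta) and updating the streaming
    accumulators. The same seed always produces bitwise-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = table.n_individuals
    alleles = np.ascontiguousarray(table.alleles, dtype=np.int32)
    J, P, Q, Z, f = _init_state(table, cfg, rng)
    het_log2 = _het_log2(table)
    alpha = 1.0

    args = (
        alleles,
        J,
        P,
        Q,
        Z,
        f,
    )
    fixed = (
        cfg.lam,
        cfg.alpha_max,
        cfg.alpha_proposal_sd,
        cfg.f_proposal_sd,
        cfg.inbreeding_mode,
        cfg.f_by_individual,
    )
    if cfg.burn_in:
        alpha = _kernels.run_sweeps(*args, alpha, *fixed, cfg.burn_in, rng)

    T = cfg.retained
    loglik_sum = np.zeros(n)
    run_max = np.full(n, -np.inf)
    run_sum = np.zeros(n)  # sum exp(x - run_max)
    trace = np.empty(T)
    mean_Q = np.zeros_like(Q)
    mean_P = np.zeros_like(P)
    mean_f = np.zeros_like(f)
    mean_alpha = 0.0
    per_ind = np.empty(n)

    for t in range(T):
        alpha = _kernels.run_sweeps(*args, alpha, *fixed, cfg.thinning, rng)
        total = _kernels.per_individual_loglik(
            alleles, J, P, Q, f, cfg.f_by_individual, het_log2, per_ind
        )
        if not np.isfinite(total):
            bad = np.flatnonzero(~np.isfinite(per_ind))
            raise FloatingPointError(
                f"non-finite likelihood at retained draw {t} "
                f"(individuals {bad[:5].tolist()}); chain aborted"
            )
        trace[t] = total
        loglik_sum += per_ind
        # streaming log-sum-exp
        grow = per_ind > run_max
        run_sum[grow] = run_sum[grow] * np.exp(run_max[grow] - per_ind[grow]) + 1.0
        run_max[grow] = per_ind[grow]
        stay = ~grow
        run_sum[stay] += np.exp(per_ind[stay] - run_max[stay])

        if cfg.relabel and cfg.K > 1 and t > 0:
            order = _match_labels(Q, mean_Q / t)
        else:
            order = np.arange(cfg.K)
        mean_Q += Q[:, order]
        mean_P += P[order]
        mean_f += f if cfg.f_by_individual else f[order]
        mean_alpha += alpha

    return ChainDraws(
        K=cfg.K,
        T=T,
        loglik_sum=loglik_sum,
        lik_logsumexp=run_max + np.log(run_sum),
        posterior_mean_Q=mean_Q / T,
        posterior_mean_f=mean_f / T,
        trace=trace,
        posterior_mean_P=mean_P / T,
        posterior_mean_alpha=mean_alpha / T,
        f_by_individual=cfg.f_by_individual,
        seed=cfg.seed,
    )


def state_deviance(table: GenotypeTable, state: ModelState) -> float:
    """Deviance ``-2 log L`` of the data at a fixed parameter point."""
    alleles = np.ascontiguousarray(table.alleles, dtype=np.int32)
    J = table.locus_allele_counts.astype(np.int64)
    out = np.empty(table.n_individuals)
    total = _kernels.per_individual_loglik(
        alleles, J, np.ascontiguousarray(state.P), np.ascontiguousarray(state.Q),
        np.ascontiguousarray(state.f), state.f_by_individual, _het_log2(table), out,
    )
    if not np.isfinite(total):
        raise ValueError("non-finite deviance at supplied state")
    return -2.0 * total


def assignment_accuracy(posterior_mean_Q: np.ndarray, true_labels) -> float:
    """Fraction of individuals whose modal cluster matches the true deme,
    maximized over cluster relabelings (label switching is a symmetry of
    the model, not an error)."""
    labels = np.asarray(true_labels)
    demes = np.unique(labels)
    k = posterior_mean_Q.shape[1]
    hard = posterior_mean_Q.argmax(axis=1)
    # confusion counts: demes x clusters, assign clusters to demes
    conf = np.zeros((len(demes), k))
    for di, d in enumerate(demes):
        sel = hard[labels == d]
        for c in range(k):
            conf[di, c] = np.sum(sel == c)
    row, col = linear_sum_assignment(-conf)
    return float(conf[row, col].sum() / len(labels))
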