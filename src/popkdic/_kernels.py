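"""Numba kernels for the admixture Gibbs sampler.

State arrays are mutated in place; all randomness flows through a single
``numpy.random.Generator`` passed in by the caller, so a chain is fully
reproducible from its seed. The latent origin pair ``Z[i, l] = (z1, z2)``
assigns each allele copy a cluster; updates enumerate all K^2 ordered cells
so the inbreeding coupling (which acts when the two origins coincide) is
handled exactly.

Genotype probabilities use the ordered-copy convention: for distinct
origins the copies are independent draws from their clusters' frequency
vectors; for a shared origin the pair is autozygous with probability given
by the inbreeding coefficient. The coefficient is either per cluster
(``f`` has length K, indexed by the shared origin) or per individual
(``f`` has length N, indexed by the individual — the granularity that
captures identity disequilibrium under partial selfing). The constant
heterozygote multiplicity (the factor 2 turning an ordered pair into an
unordered genotype) is applied once at likelihood recording time, where it
cannot bias the origin updates.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _pair_prob(a, b, k1, k2, P, l, fv):
    """Ordered-pair genotype probability; missing copies contribute 1.

    ``fv`` is the inbreeding coefficient applying if ``k1 == k2``.
    """
    if a < 0 and b < 0:
        return 1.0
    if a < 0:
        return P[k2, l, b]
    if b < 0:
        return P[k1, l, a]
    if k1 == k2:
        pa = P[k1, l, a]
        if a == b:
            return fv * pa + (1.0 - fv) * pa * pa
        return (1.0 - fv) * pa * P[k1, l, b]
    return P[k1, l, a] * P[k2, l, b]


@njit(cache=True)
def run_sweeps(
    alleles,
    J,
    P,
    Q,
    Z,
    f,
    alpha,
    lam,
    alpha_max,
    alpha_sd,
    f_sd,
    inbreeding,
    f_by_individual,
    n_sweeps,
    rng,
):
    """Run ``n_sweeps`` full Gibbs sweeps, returning the updated alpha.

    One sweep: exact conditional redraw of every origin pair (K^2 cells),
    conjugate Dirichlet redraws of P and Q from current assignment counts,
    a Metropolis step on alpha (uniform prior on (0, alpha_max]), and, in
    inbreeding mode, one Metropolis step per inbreeding coefficient
    (uniform (0,1) prior) — per cluster or per individual according to
    ``f_by_individual``.
    """
    N, L, _ = alleles.shape
    K = Q.shape[1]
    w = np.empty(K * K)
    nf = f.shape[0]
    fprop = np.empty(nf)
    fdelta = np.empty(nf)

    for _ in range(n_sweeps):
        allele_counts = np.zeros((K, L, P.shape[2]))
        origin_counts = np.zeros((N, K))

        # --- origin pairs Z, with count accumulation
        for i in range(N):
            fi = f[i] if f_by_individual else 0.0
            for l in range(L):
                a = alleles[i, l, 0]
                b = alleles[i, l, 1]
                tot = 0.0
                idx = 0
                for k1 in range(K):
                    qk1 = Q[i, k1]
                    fv = fi if f_by_individual else f[k1]
                    for k2 in range(K):
                        v = qk1 * Q[i, k2] * _pair_prob(a, b, k1, k2, P, l, fv)
                        w[idx] = v
                        tot += v
                        idx += 1
                if not tot > 0.0:
                    raise ValueError(
                        "all K^2 origin cells have zero probability"
                    )
                u = rng.random() * tot
                acc = 0.0
                sel = K * K - 1
                for idx in range(K * K):
                    acc += w[idx]
                    if u < acc:
                        sel = idx
                        break
                k1 = sel // K
                k2 = sel % K
                Z[i, l, 0] = k1
                Z[i, l, 1] = k2
                origin_counts[i, k1] += 1.0
                origin_counts[i, k2] += 1.0
                if a >= 0:
                    allele_counts[k1, l, a] += 1.0
                if b >= 0:
                    allele_counts[k2, l, b] += 1.0

        # --- allele frequencies: P(k,l,.) ~ Dirichlet(lam + counts)
        for k in range(K):
            for l in range(L):
                s = 0.0
                for j in range(J[l]):
                    g = rng.standard_gamma(lam + allele_counts[k, l, j])
                    P[k, l, j] = g
                    s += g
                for j in range(J[l]):
                    P[k, l, j] /= s

        # --- admixture proportions: Q(i,.) ~ Dirichlet(alpha + counts)
        for i in range(N):
            s = 0.0
            for k in range(K):
                g = rng.standard_gamma(alpha + origin_counts[i, k])
                Q[i, k] = g
                s += g
            for k in range(K):
                Q[i, k] /= s

        # --- alpha: random-walk Metropolis under Uniform(0, alpha_max]
        prop = alpha + alpha_sd * rng.standard_normal()
        if 0.0 < prop <= alpha_max:
            slogq = 0.0
            for i in range(N):
                for k in range(K):
                    q = Q[i, k]
                    if q < 1e-300:
                        q = 1e-300
                    slogq += math.log(q)
            lp_cur = N * (math.lgamma(K * alpha) - K * math.lgamma(alpha)) + (
                alpha - 1.0
            ) * slogq
            lp_prop = N * (math.lgamma(K * prop) - K * math.lgamma(prop)) + (
                prop - 1.0
            ) * slogq
            if math.log(rng.random()) < lp_prop - lp_cur:
                alpha = prop

        # --- inbreeding coefficients: Metropolis on each f entry
        if inbreeding:
            for j in range(nf):
                fprop[j] = f[j] + f_sd * rng.standard_normal()
                fdelta[j] = 0.0
            for i in range(N):
                for l in range(L):
                    k1 = Z[i, l, 0]
                    if k1 != Z[i, l, 1]:
                        continue
                    a = alleles[i, l, 0]
                    b = alleles[i, l, 1]
                    if a < 0 or b < 0:
                        continue  # f only couples fully observed pairs
                    j = i if f_by_individual else k1
                    fp = fprop[j]
                    if fp < 0.0 or fp >= 1.0:
                        continue
                    if a == b:
                        pa = P[k1, l, a]
                        cur = f[j] * pa + (1.0 - f[j]) * pa * pa
                        new = fp * pa + (1.0 - fp) * pa * pa
                        fdelta[j] += math.log(new / cur)
                    else:
                        fdelta[j] += math.log((1.0 - fp) / (1.0 - f[j]))
            for j in range(nf):
                if fprop[j] < 0.0 or fprop[j] >= 1.0:
                    continue  # outside prior support: auto-reject
                if math.log(rng.random()) < fdelta[j]:
                    f[j] = fprop[j]
    return alpha


@njit(cache=True)
def per_individual_loglik(alleles, J, P, Q, f, f_by_individual, het_log2, out):
    """Origin-marginalized log-likelihood per individual.

    ``out[i] = sum_l log( mult_l * sum_{k1,k2} Q[i,k1] Q[i,k2] pr(a,b|k1,k2) )``
    where ``mult_l`` (passed as ``het_log2``, log of 1 or 2) converts the
    ordered-pair probability into the unordered observed-genotype
    probability. Returns the total over individuals.
    """
    N, L, _ = alleles.shape
    K = Q.shape[1]
    total = 0.0
    for i in range(N):
        s = 0.0
        fi = f[i] if f_by_individual else 0.0
        for l in range(L):
            a = alleles[i, l, 0]
            b = alleles[i, l, 1]
            m = 0.0
            for k1 in range(K):
                qk1 = Q[i, k1]
                fv = fi if f_by_individual else f[k1]
                for k2 in range(K):
                    m += qk1 * Q[i, k2] * _pair_prob(a, b, k1, k2, P, l, fv)
            s += math.log(m) + het_log2[i, l]
        out[i] = s
        total += s
    return total
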