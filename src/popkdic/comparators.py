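"""Competing estimators of the number of clusters K.

Three comparators evaluated alongside DIC:

* ``lnpk_estimate`` — the approximate posterior log-probability of the data
  given K popularized by STRUCTURE: mean retained log-likelihood minus half
  its variance; K is chosen by maximizing the across-chain mean.
* ``evanno_delta_k`` — the ad hoc second-difference statistic dK: the
  across-chain mean absolute second difference of L(K), divided by the
  across-chain standard deviation of L(K); peaks at the inferred K and is
  undefined at the edges of the K grid (so K = 1 is never selectable).
* ``tw_eigen_k`` — eigenanalysis of the scaled genotype matrix: K is 1 plus
  the number of leading eigenvalues of the sample covariance that are
  significant under the Tracy-Widom (TW1) distribution, tested sequentially
  with a moment-based effective-marker-count correction.

These comparators consume this package's own sampler output, not the
external programs' — benchmark tables test the statistics, not the
programs that popularized them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeTable

# Upper-tail critical values of the Tracy-Widom TW1 (GOE) distribution.
# (significance level, critical value); interpolated log-linearly between.
_TW1_TAIL = [
    (0.10, 0.4501),
    (0.05, 0.9793),
    (0.025, 1.4538),
    (0.01, 2.0234),
    (0.005, 2.4224),
    (0.001, 3.2724),
]


def tw1_critical(alpha: float) -> float:
    """TW1 critical value at upper-tail significance ``alpha``."""
    levels = np.array([a for a, _ in _TW1_TAIL])
    crits = np.array([c for _, c in _TW1_TAIL])
    if not (levels.min() <= alpha <= levels.max()):
        raise ValueError(
            f"alpha {alpha} outside tabulated range [{levels.min()}, {levels.max()}]"
        )
    return float(np.interp(np.log(alpha), np.log(levels[::-1]), crits[::-1]))


def lnpk_estimate(trace: np.ndarray) -> float:
    """Approximate ln P(X | K) from the retained log-likelihood trace.

    Returns ``mean - var/2`` with the sample variance (denominator T - 1).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("need at least 2 retained draws")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


@dataclass
class DeltaKResult:
    k_values: np.ndarray  # interior K values where dK is defined
    delta_k: np.ndarray
    selected_K: int


def evanno_delta_k(L: np.ndarray, k_grid: np.ndarray | list) -> DeltaKResult:
    """Second-difference statistic over a chains x K matrix of L(K).

    Per chain r the absolute second difference |L_r(K+1) - 2 L_r(K) +
    L_r(K-1)| is formed; dK at interior K is the mean of these over chains
    divided by the across-chain standard deviation of L(K). The selected K
    maximizes dK (ties toward smaller K).
    """
    L = np.asarray(L, dtype=float)
    k_grid = np.asarray(k_grid)
    if L.ndim != 2 or L.shape[1] != len(k_grid):
        raise ValueError("L must be chains x len(k_grid)")
    if L.shape[0] < 2:
        raise ValueError("need >= 2 chains for the across-chain sd")
    if len(k_grid) < 3 or (np.diff(k_grid) != 1).any():
        raise ValueError("need >= 3 consecutive K values")
    second = np.abs(L[:, 2:] - 2 * L[:, 1:-1] + L[:, :-2])  # chains x interior
    sd = L.std(axis=0, ddof=1)[1:-1]
    if (sd == 0).any():
        raise ValueError("zero across-chain sd of L(K): delta-K undefined")
    dk = second.mean(axis=0) / sd
    interior = k_grid[1:-1]
    sel = int(interior[np.argmax(dk)])
    return DeltaKResult(k_values=interior, delta_k=dk, selected_K=sel)


def _scaled_dosage_columns(table: GenotypeTable) -> np.ndarray:
    """Column-normalized genotype matrix for eigenanalysis.

    Diallelic loci contribute one column of allele-1 dosage; multi-allelic
    loci are expanded to one dosage column per allele. Columns are centered
    and scaled by the binomial sd sqrt(p(1-p)) with p the mean dosage / 2;
    monomorphic columns are dropped, missing entries mean-imputed (zero
    after centering).
    """
    cols = []
    for l in range(table.n_loci):
        j = int(table.locus_allele_counts[l])
        geno = table.alleles[:, l, :]
        alleles = [1] if j <= 2 else range(j)
        for al in alleles:
            miss = (geno < 0).any(axis=1)
            d = (geno == al).sum(axis=1).astype(float)
            d[miss] = np.nan
            cols.append(d)
    X = np.array(cols).T  # N x columns
    mu = np.nanmean(X, axis=0)
    p = mu / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} monomorphic column(s) from eigenanalysis"
        )
    if not keep.any():
        raise ValueError("all columns monomorphic; eigenanalysis impossible")
    X = (X[:, keep] - mu[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    return np.nan_to_num(X, nan=0.0)


def tw_eigen_k(table: GenotypeTable, alpha: float = 0.05, min_m: int = 3) -> int:
    """Estimate K as 1 + the number of significant covariance eigenvalues.

    Eigenvalues of the individual x individual covariance of the scaled
    genotype matrix are tested largest-first: with ``m`` eigenvalues
    remaining, the effective marker count is estimated by moments,

        n_eff = (m + 1) (sum l)^2 / ((m - 1) sum l^2 - (sum l)^2),

    the top eigenvalue is normalized as ``m * l_1 / sum l`` and centered and
    scaled by the Tracy-Widom constants for an (n_eff, m) white Wishart;
    testing stops at the first non-significant eigenvalue.
    """
    if table.n_individuals < 3:
        raise ValueError("need more than 2 individuals")
    X = _scaled_dosage_columns(table)
    n, l_cols = X.shape
    cov = X @ X.T / l_cols
    evals = np.linalg.eigvalsh(cov)[::-1][: n - 1]  # drop the ~0 centering mode
    crit = tw1_critical(alpha)
    k_hat = 1
    evals = list(evals)
    while len(evals) >= min_m:
        m = len(evals)
        y = float(np.sum(evals))
        y2 = float(np.sum(np.square(evals)))
        denom = (m - 1) * y2 - y * y
        if denom <= 0 or y <= 0:
            break
        n_eff = (m + 1) * y * y / denom
        if n_eff <= 1:
            break
        l1 = m * evals[0] / y
        mu = (np.sqrt(n_eff - 1) + np.sqrt(m)) ** 2 / n_eff
        sigma = (
            (np.sqrt(n_eff - 1) + np.sqrt(m))
            / n_eff
            * (1.0 / np.sqrt(n_eff - 1) + 1.0 / np.sqrt(m)) ** (1.0 / 3.0)
        )
        if (l1 - mu) / sigma <= crit:
            break
        k_hat += 1
        evals.pop(0)
    return k_hat
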