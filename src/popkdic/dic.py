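"""Deviance Information Criterion for the admixture mixture model.

DIC = Dbar + pD, where Dbar is the posterior mean deviance and pD the
effective number of parameters, estimated as Dbar - Dhat. The classic
plug-in Dhat evaluates the deviance at a posterior point estimate, which
is ill-behaved for mixtures because of label switching. The stabilized
mixture variant instead averages each individual's *likelihood* over
retained draws,

    Dhat = -2 sum_i log( (1/T) sum_t f_i(theta_t) ),

which is invariant under cluster relabeling because f_i itself is. Jensen's
inequality makes the resulting pD non-negative. Smaller DIC indicates a
better-fitting model; K is selected by minimizing, taking the minimum over
chains first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import ChainDraws, ModelState, state_deviance

PANEL_COLUMNS = ["K", "chain", "Dbar", "Dhat", "pD", "DIC"]


@dataclass
class KSelectionResult:
    selected_K: int
    dic_by_k: dict[int, float]
    chain_of_minimum: int

    def to_dict(self) -> dict:
        return {
            "selected_K": self.selected_K,
            "dic_by_k": {str(k): v for k, v in self.dic_by_k.items()},
            "chain_of_minimum": self.chain_of_minimum,
        }


def dbar(draws: ChainDraws) -> float:
    """Posterior mean deviance: -2 mean over draws of the total log-likelihood."""
    if draws.T < 1:
        raise ValueError("need at least one retained draw")
    return float(-2.0 * np.sum(draws.loglik_sum / draws.T))


def dic_stable(draws: ChainDraws, K: int | None = None, chain: int = 0) -> pd.Series:
    """Stabilized DIC row (Dbar, Dhat, pD, DIC) from chain accumulators."""
    if draws.T < 1:
        raise ValueError("need at least one retained draw")
    avg_log_lik = draws.lik_logsumexp - np.log(draws.T)
    if not np.isfinite(avg_log_lik).all():
        bad = np.flatnonzero(~np.isfinite(avg_log_lik))
        raise ValueError(f"non-finite likelihood accumulator for individuals {bad[:5].tolist()}")
    d_bar = dbar(draws)
    d_hat = float(-2.0 * np.sum(avg_log_lik))
    p_d = d_bar - d_hat
    return pd.Series(
        {
            "K": K if K is not None else draws.K,
            "chain": chain,
            "Dbar": d_bar,
            "Dhat": d_hat,
            "pD": p_d,
            "DIC": d_bar + p_d,
        }
    )


def dic_plugin(draws: ChainDraws, table, point: ModelState) -> float:
    """Classic plug-in DIC = 2 Dbar - D(theta_hat) at a supplied point.

    Provided for comparison only: unless the chain (and the point) have
    been consistently relabeled, label switching makes this estimator
    erratic for mixtures.
    """
    return 2.0 * dbar(draws) - state_deviance(table, point)


def deviance_panel(chains: dict[tuple[int, int], ChainDraws]) -> pd.DataFrame:
    """Assemble per-(K, chain) DIC rows into a panel.

    ``chains`` maps (K, chain index) to that chain's accumulators.
    """
    rows = [dic_stable(d, K=k, chain=c) for (k, c), d in sorted(chains.items())]
    return pd.DataFrame(rows)[PANEL_COLUMNS]


def select_k(panel: pd.DataFrame) -> KSelectionResult:
    """Select K minimizing DIC, taking the minimum over chains per K.

    Exact ties break toward smaller K. Multimodal likelihood surfaces make
    DIC vary across chains for the same K, so the per-K minimum (the best
    fit any chain found) is the robust summary.
    """
    if len(panel) == 0:
        raise ValueError("empty deviance panel")
    best = panel.loc[panel.groupby("K")["DIC"].idxmin()]
    dic_by_k = {int(r.K): float(r.DIC) for r in best.itertuples()}
    ks = sorted(dic_by_k)
    sel = min(ks, key=lambda k: (dic_by_k[k], k))
    chain_min = int(best.loc[best.K == sel, "chain"].iloc[0])
    return KSelectionResult(selected_K=int(sel), dic_by_k=dic_by_k, chain_of_minimum=chain_min)
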