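"""Replicate simulation -> multi-chain fitting -> K-selection accuracy.

Mirrors the accuracy-study design used to compare K-estimators: for each
demographic scenario, simulate replicate datasets, fit the admixture
sampler over a grid of K with several chains each, apply each criterion,
and report the fraction of replicates recovering the true K. At full
scale the study uses 50 replicates, 5 chains and a 500k/50k/10 schedule;
the scaled-down profile (10 replicates, 3 chains, 20k burn-in, 2000
retained, thinning 10) is the default here.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import comparators, dic
from .mcmc import ChainConfig, run_chain
from .simulate import DemographicModel, SimConfig, simulate_dataset

log = logging.getLogger(__name__)

#: scaled-down chain schedule (full-scale: burn_in=500000, retained=50000)
SCALED_DOWN_PROFILE = ChainConfig(burn_in=20_000, retained=2_000, thinning=10)

EIGEN_ALPHAS = (0.05, 0.01, 0.001)


@dataclass
class ScenarioSpec:
    model: DemographicModel
    true_k: int
    replicates: int = 10
    individuals_per_deme: int = 50
    n_loci: int = 100
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    chains: int = 3
    chain_profile: ChainConfig = field(default_factory=lambda: SCALED_DOWN_PROFILE)
    criteria: tuple[str, ...] = ("dic", "lnpk", "deltak", "eigen")
    #: None: inbreeding mode follows the data-generating model — on, at
    #: individual granularity, for the selfing scenario (partial selfing
    #: creates identity disequilibrium, which a per-cluster coefficient
    #: cannot absorb), off otherwise (an unidentified f only adds Monte
    #: Carlo noise to the K comparison on outbred data).
    inbreeding_mode: bool | None = None
    inbreeding_granularity: str | None = None
    base_seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.true_k not in self.k_grid:
            raise ValueError("K grid must cover the true K")
        if self.true_k != self.model.n_demes:
            raise ValueError("true_k must equal model.n_demes")


@dataclass
class AccuracyTable:
    """Per-criterion accuracy plus replicate-level records."""

    scenario: str
    true_k: int
    accuracy: dict[str, float]
    mean_fst: float | None
    records: pd.DataFrame
    n_valid: int
    n_invalid: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": self.scenario,
                "true_k": self.true_k,
                "criterion": c,
                "accuracy": a,
                "mean_fst": self.mean_fst,
                "n_valid": self.n_valid,
                "n_invalid": self.n_invalid,
            }
            for c, a in sorted(self.accuracy.items())
        ]
        return pd.DataFrame(rows)


def _criterion_names(criteria) -> list[str]:
    out = []
    for c in criteria:
        if c == "eigen":
            out.extend(f"eigen_{a}" for a in EIGEN_ALPHAS)
        else:
            out.append(c)
    return out


def run_replicate(spec: ScenarioSpec, replicate: int) -> dict:
    """Simulate one dataset, fit all chains over the K grid, apply criteria.

    Returns a record with the selected K per criterion. Seeds:
    replicate seed = base_seed + replicate; chain seed = replicate seed *
    1000 + chain index.
    """
    rep_seed = spec.base_seed + replicate
    table, summary = simulate_dataset(
        spec.model,
        SimConfig(
            individuals_per_deme=spec.individuals_per_deme,
            n_loci=spec.n_loci,
            seed=rep_seed,
        ),
    )
    record: dict = {
        "replicate": replicate,
        "seed": rep_seed,
        "true_k": spec.true_k,
        "fst": summary.mean_pairwise_fst,
    }

    inbreeding = (
        spec.inbreeding_mode
        if spec.inbreeding_mode is not None
        else spec.model.kind == "inbred"
    )
    granularity = spec.inbreeding_granularity or (
        "individual" if spec.model.kind == "inbred" else "cluster"
    )
    mcmc_criteria = {"dic", "lnpk", "deltak"} & set(spec.criteria)
    if mcmc_criteria:
        chains: dict[tuple[int, int], object] = {}
        for k in spec.k_grid:
            for c in range(spec.chains):
                cfg = replace(
                    spec.chain_profile,
                    K=k,
                    seed=rep_seed * 1000 + c,
                    inbreeding_mode=inbreeding,
                    inbreeding_granularity=granularity,
                )
                t0 = time.perf_counter()
                chains[(k, c)] = run_chain(table, cfg)
                log.debug(
                    "replicate %d K=%d chain %d: %.1fs",
                    replicate, k, c, time.perf_counter() - t0,
                )
        if "dic" in mcmc_criteria:
            panel = dic.deviance_panel(chains)
            record["dic"] = dic.select_k(panel).selected_K
        if {"lnpk", "deltak"} & mcmc_criteria:
            ks = sorted(spec.k_grid)
            L = np.array(
                [
                    [comparators.lnpk_estimate(chains[(k, c)].trace) for k in ks]
                    for c in range(spec.chains)
                ]
            )
            if "lnpk" in mcmc_criteria:
                mean_l = L.mean(axis=0)
                record["lnpk"] = int(ks[int(np.argmax(mean_l))])
            if "deltak" in mcmc_criteria:
                try:
                    record["deltak"] = comparators.evanno_delta_k(L, ks).selected_K
                except ValueError:
                    record["deltak"] = None

    if "eigen" in spec.criteria:
        for a in EIGEN_ALPHAS:
            try:
                record[f"eigen_{a}"] = comparators.tw_eigen_k(table, alpha=a)
            except ValueError:
                record[f"eigen_{a}"] = None
    return record


def run_scenario(spec: ScenarioSpec) -> AccuracyTable:
    """Run all replicates of a scenario and summarize accuracy.

    A replicate whose fit fails is recorded as invalid and excluded from
    the accuracy denominator (and reported).
    """
    records, invalid = [], 0
    for r in range(spec.replicates):
        try:
            records.append(run_replicate(spec, r))
        except (FloatingPointError, ValueError) as exc:
            invalid += 1
            log.warning("replicate %d invalid: %s", r, exc)
            records.append(
                {"replicate": r, "seed": spec.base_seed + r, "true_k": spec.true_k,
                 "fst": None, "invalid": str(exc)}
            )
    df = pd.DataFrame(records)
    valid = df[df["invalid"].isna()] if "invalid" in df.columns else df
    names = _criterion_names(spec.criteria)
    accuracy = {}
    for c in names:
        if c in valid:
            sel = valid[c].dropna()
            accuracy[c] = float((sel == spec.true_k).sum() / len(valid)) if len(valid) else np.nan
    fsts = valid["fst"].dropna() if "fst" in valid else pd.Series(dtype=float)
    return AccuracyTable(
        scenario=spec.name or f"{spec.model.kind}_K{spec.true_k}",
        true_k=spec.true_k,
        accuracy=accuracy,
        mean_fst=float(fsts.mean()) if len(fsts) else None,
        records=df,
        n_valid=len(valid),
        n_invalid=invalid,
    )


def accuracy_table(tables: list[AccuracyTable]) -> pd.DataFrame:
    """Combine scenarios into one criterion x scenario accuracy table."""
    frames = [t.to_frame() for t in tables]
    long = pd.concat(frames, ignore_index=True)
    return long.pivot_table(
        index="criterion", columns="scenario", values="accuracy", aggfunc="first"
    )
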