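"""Config-driven named experiments contrasting the two perspectives.

Each experiment wires the analytics and simulators into one of the studies
the package is built around (feedback-strength sweeps, cycle-noise sweeps,
burst-size vs partitioning-noise decomposition, divergence and equivalence
regimes) at desk scale, and returns tidy DataFrames; ``run_experiment``
writes them as TSV next to a JSON log and a copy of the resolved config.

Default replicate counts follow the study protocol (5000 lineages, 2000
colonies, 6 generations); ``fast=True`` runs at one tenth of that for quick
checks.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import analytics, colony_sim, estimators, lineage_sim
from .analytics import Perspective, StationaryLaw
from .colony_sim import StopRule, colony_ensemble, population_stats
from .estimators import summary_stats
from .lineage_sim import feedback_endpoint_ensemble, partitioning_endpoint_ensemble
from .model_core import (
    LN2,
    BurstFeedbackParams,
    CycleModel,
    PartitionModel,
    spawn_generators,
)

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    experiment: str
    seed: int = 0
    out_dir: Optional[str] = None
    fast: bool = False
    # model parameters (defaults: the feedback configuration with mean 100)
    beta: float = 10.0
    gamma: float = 1.0
    k: float = 0.01
    target_mean: float = 100.0
    epsilon: float = 1.0
    degradation: float = 0.0
    # replicate counts / horizons
    n_lineages: int = 5000
    n_colonies: int = 2000
    n_generations: int = 6
    burn_in: float = 50.0
    # sweep axes (experiment-specific; None = experiment default)
    sweep: Optional[list] = None

    def scale(self, n: int) -> int:
        return max(10, n // 10) if self.fast else n

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(f"unknown config keys: {', '.join(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _feedback_params(cfg: ExperimentConfig, k: float) -> BurstFeedbackParams:
    lam = analytics.burst_frequency_for_mean(cfg.target_mean, k, cfg.beta, cfg.gamma)
    return BurstFeedbackParams(lam=lam, beta=cfg.beta, gamma=cfg.gamma, k=k,
                               d=cfg.degradation)


def _partition_setup(cfg: ExperimentConfig, mean: float, beta: Optional[float] = None):
    """Partitioning-model pieces: gamma = ln2 time units, fixed-point mean."""
    g = LN2
    b = beta if beta is not None else cfg.beta
    lam = g * mean / b
    params = BurstFeedbackParams(lam=lam, beta=b, gamma=g, k=0.0)
    part = PartitionModel(epsilon=cfg.epsilon)
    return params, part


def feedback_sweep(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Analytic + simulated statistics of both perspectives over k (fixed SC mean)."""
    ks = cfg.sweep or [0.0, 0.002, 0.005, 0.01, 0.02]
    n_lin = cfg.scale(cfg.n_lineages)
    n_col = cfg.scale(cfg.n_colonies)
    rows = []
    for i, k in enumerate(ks):
        params = _feedback_params(cfg, k)
        sc_th = analytics.moments(params, Perspective.SINGLE_CELL)
        pop_th = analytics.moments(params, Perspective.POPULATION)
        ends = feedback_endpoint_ensemble(
            params, n_lin, t_end=cfg.burn_in, seed=(cfg.seed, 2 * i)
        )
        sc_sim = summary_stats(ends, n_boot=100, seed=cfg.seed)
        snaps = colony_ensemble(
            params,
            CycleModel(kind="hazard_feedback"),
            StopRule(time=8.0 / cfg.gamma),
            n_colonies=n_col,
            seed=(cfg.seed, 2 * i + 1),
            x0_sampler=StationaryLaw(params, Perspective.SINGLE_CELL).sample_one,
        )
        pop_sim = population_stats(snaps, seed=cfg.seed)
        for tag, th, sim in (
            ("single_cell", sc_th, sc_sim),
            ("population", pop_th, pop_sim),
        ):
            rows.append(dict(k=k, lam=params.lam, perspective=tag,
                             mean_theory=th.mean, cv2_theory=th.cv2,
                             skew_theory=th.skew, n=sim.n, mean=sim.mean,
                             cv2=sim.cv2, skew=sim.skew, se_mean=sim.se_mean,
                             se_cv2=sim.se_cv2, se_skew=sim.se_skew))
    return {"stats": pd.DataFrame(rows)}


def cycle_noise_sweep(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """CV^2 of both perspectives vs cell-cycle-time noise (partitioning model)."""
    cv2_taus = cfg.sweep or [0.0, 0.25, 0.5, 1.0]
    mean = 20.0 if cfg.target_mean == 100.0 else cfg.target_mean
    params, part = _partition_setup(cfg, mean)
    pred = analytics.predicted_partition_cv2(mean, cfg.epsilon, 0.0)
    n_lin = cfg.scale(cfg.n_lineages)
    n_col = cfg.scale(cfg.n_colonies)
    rows = []
    for i, c in enumerate(cv2_taus):
        cyc = CycleModel(kind="timer", cv2_tau=c)
        ends = partitioning_endpoint_ensemble(
            params, part, cyc, n_lin, n_generations=cfg.n_generations,
            seed=(cfg.seed, 2 * i),
        )
        sc = summary_stats(ends, n_boot=100, seed=cfg.seed)
        snaps = colony_ensemble(
            params, cyc, StopRule(generations=cfg.n_generations),
            n_colonies=n_col, partition=part, seed=(cfg.seed, 2 * i + 1),
            expression="deterministic",
        )
        pop = population_stats(snaps, seed=cfg.seed)
        for tag, s in (("single_cell", sc), ("population", pop)):
            rows.append(dict(cv2_tau=c, perspective=tag, cv2_predicted_sc=pred,
                             n=s.n, mean=s.mean, cv2=s.cv2, skew=s.skew,
                             se_mean=s.se_mean, se_cv2=s.se_cv2))
    return {"stats": pd.DataFrame(rows)}


def mean_scaling(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """CV^2 vs mean on log axes (inverse scaling), both perspectives."""
    means = cfg.sweep or [5.0, 10.0, 20.0, 40.0, 80.0]
    n_lin = cfg.scale(cfg.n_lineages) // 2
    n_col = cfg.scale(cfg.n_colonies) // 2
    cyc = CycleModel(kind="timer", cv2_tau=1.0)
    rows = []
    for i, m in enumerate(means):
        params, part = _partition_setup(cfg, m)
        ends = partitioning_endpoint_ensemble(
            params, part, cyc, n_lin, n_generations=cfg.n_generations,
            seed=(cfg.seed, 2 * i),
        )
        sc = summary_stats(ends, n_boot=100, seed=cfg.seed)
        snaps = colony_ensemble(
            params, cyc, StopRule(generations=cfg.n_generations),
            n_colonies=n_col, partition=part, seed=(cfg.seed, 2 * i + 1),
            expression="deterministic",
        )
        pop = population_stats(snaps, seed=cfg.seed)
        for tag, s in (("single_cell", sc), ("population", pop)):
            rows.append(dict(mean_target=m, perspective=tag,
                             cv2_predicted_sc=analytics.predicted_partition_cv2(
                                 m, cfg.epsilon, 0.0),
                             n=s.n, mean=s.mean, cv2=s.cv2, se_cv2=s.se_cv2))
    return {"stats": pd.DataFrame(rows)}


def burst_vs_partition(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """CV^2 vs mean burst size at fixed partitioning noise (bursty expression)."""
    betas = cfg.sweep or [0.2, 1.0, 5.0]
    mean = 20.0 if cfg.target_mean == 100.0 else cfg.target_mean
    cyc = CycleModel(kind="timer", cv2_tau=1.0)
    n_lin = cfg.scale(cfg.n_lineages)
    n_col = cfg.scale(cfg.n_colonies) // 2
    rows = []
    for i, b in enumerate(betas):
        params, part = _partition_setup(cfg, mean, beta=b)
        pred = analytics.predicted_partition_cv2(mean, cfg.epsilon, b)
        ends = partitioning_endpoint_ensemble(
            params, part, cyc, n_lin, n_generations=cfg.n_generations,
            seed=(cfg.seed, 2 * i), bursty=True,
        )
        sc = summary_stats(ends, n_boot=100, seed=cfg.seed)
        snaps = colony_ensemble(
            params, cyc, StopRule(generations=cfg.n_generations),
            n_colonies=n_col, partition=part, seed=(cfg.seed, 2 * i + 1),
            expression="bursty",
        )
        pop = population_stats(snaps, seed=cfg.seed)
        for tag, s in (("single_cell", sc), ("population", pop)):
            rows.append(dict(beta=b, perspective=tag, cv2_predicted_sc=pred,
                             n=s.n, mean=s.mean, cv2=s.cv2, se_cv2=s.se_cv2))
    return {"stats": pd.DataFrame(rows)}


def divergence(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Regime where only the population law exists: lineage mean grows, pool plateaus."""
    params = BurstFeedbackParams(lam=1.2 * cfg.gamma, beta=10.0, gamma=cfg.gamma, k=0.2)
    checkpoints = cfg.sweep or [5.0, 10.0, 15.0]
    n_lin = cfg.scale(cfg.n_lineages) // 5
    n_col = cfg.scale(cfg.n_colonies) // 4
    pop_th = analytics.moments(params, Perspective.POPULATION)
    rows = []
    for i, T in enumerate(checkpoints):
        ends = feedback_endpoint_ensemble(params, n_lin, t_end=T,
                                          seed=(cfg.seed, 2 * i))
        sc = summary_stats(ends, n_boot=100, seed=cfg.seed)
        snaps = colony_ensemble(
            params, CycleModel(kind="hazard_feedback"), StopRule(time=T),
            n_colonies=n_col, seed=(cfg.seed, 2 * i + 1),
        )
        pop = population_stats(snaps, seed=cfg.seed)
        rows.append(dict(time=T, sc_mean=sc.mean, sc_se=sc.se_mean,
                         pop_mean=pop.mean, pop_se=pop.se_mean,
                         pop_mean_theory=pop_th.mean))
    return {"stats": pd.DataFrame(rows)}


def equivalence_checks(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Regimes where both perspectives coincide.

    (a) deterministic timer (cycle noise zero) in the partitioning model;
    (b) constant dilution/division with concentration-dependent burst
        frequency (growth-coupled bursts, no dilution feedback).
    """
    rows = []
    mean = 20.0 if cfg.target_mean == 100.0 else cfg.target_mean
    params, part = _partition_setup(cfg, mean)
    cyc0 = CycleModel(kind="timer", cv2_tau=0.0)
    n_lin = cfg.scale(cfg.n_lineages)
    n_col = cfg.scale(cfg.n_colonies)
    ends = partitioning_endpoint_ensemble(
        params, part, cyc0, n_lin, n_generations=cfg.n_generations,
        seed=(cfg.seed, 0),
    )
    sc = summary_stats(ends, n_boot=100, seed=cfg.seed)
    snaps = colony_ensemble(
        params, cyc0, StopRule(generations=cfg.n_generations), n_colonies=n_col,
        partition=part, seed=(cfg.seed, 1), expression="deterministic",
    )
    pop = population_stats(snaps, seed=cfg.seed)
    rows.append(dict(check="fixed_cycle_time", sc_cv2=sc.cv2, sc_se=sc.se_cv2,
                     pop_cv2=pop.cv2, pop_se=pop.se_cv2))
    # constant dilution, x-dependent burst rate
    p2 = BurstFeedbackParams(
        lam=analytics.burst_frequency_for_mean(mean, 0.05, cfg.beta, cfg.gamma)
        * (1.0),
        beta=cfg.beta, gamma=cfg.gamma, k=0.05,
        burst_mode="growth_coupled", dilution_mode="constant",
    )
    ends = feedback_endpoint_ensemble(p2, n_lin, t_end=cfg.burn_in // 2,
                                      seed=(cfg.seed, 2))
    sc2 = summary_stats(ends, n_boot=100, seed=cfg.seed)
    snaps2 = colony_ensemble(
        p2, CycleModel(kind="hazard_feedback"), StopRule(time=6.0 / cfg.gamma),
        n_colonies=n_col // 2, seed=(cfg.seed, 3),
    )
    pop2 = population_stats(snaps2, seed=cfg.seed)
    rows.append(dict(check="constant_dilution_xdep_bursts", sc_cv2=sc2.cv2,
                     sc_se=sc2.se_cv2, pop_cv2=pop2.cv2, pop_se=pop2.se_cv2))
    return {"stats": pd.DataFrame(rows)}


def degradation_sweep(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Short-lived protein: as d >> gamma both perspectives approach a gamma law."""
    ds = cfg.sweep or [0.0, 2.0, 20.0]
    n_lin = cfg.scale(cfg.n_lineages) // 2
    rows = []
    for i, d in enumerate(ds):
        base = _feedback_params(cfg, cfg.k)
        params = dataclasses.replace(base, d=d)
        t_relax = 10.0 / (cfg.gamma + d)
        ends = feedback_endpoint_ensemble(params, n_lin, t_end=5.0 + t_relax,
                                          seed=(cfg.seed, i))
        sc = summary_stats(ends)
        # unregulated reference: shape lam/(gamma+d), scale beta
        from scipy import stats as sps

        shape = params.lam / (cfg.gamma + d)
        ref = sps.gamma(shape, scale=cfg.beta)
        ksd = estimators.ks_distance(ends, ref.cdf)
        rows.append(dict(d=d, mean=sc.mean, cv2=sc.cv2,
                         ks_to_unregulated_gamma=ksd))
    return {"stats": pd.DataFrame(rows)}


def growth_coupled(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Burst frequency proportional to the growth rate: perspective gap shrinks."""
    base = _feedback_params(cfg, cfg.k)
    params = dataclasses.replace(base, burst_mode="growth_coupled")
    n_lin = cfg.scale(cfg.n_lineages)
    n_col = cfg.scale(cfg.n_colonies) // 2
    ends = feedback_endpoint_ensemble(params, n_lin, t_end=cfg.burn_in,
                                      seed=(cfg.seed, 0))
    sc = summary_stats(ends, n_boot=100, seed=cfg.seed)
    snaps = colony_ensemble(
        params, CycleModel(kind="hazard_feedback"), StopRule(time=8.0 / cfg.gamma),
        n_colonies=n_col, seed=(cfg.seed, 1),
        x0_sampler=lambda rng: float(np.clip(rng.normal(sc.mean, sc.mean / 2), 0, None)),
    )
    pop = population_stats(snaps, seed=cfg.seed)
    cmp_ = estimators.compare_perspectives(sc, pop)
    df = pd.DataFrame([dict(sc_mean=sc.mean, pop_mean=pop.mean,
                            mean_ratio=cmp_.ratio_mean, sc_cv2=sc.cv2,
                            pop_cv2=pop.cv2, cv2_ratio=cmp_.ratio_cv2)])
    return {"stats": df}


def adder(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Adder size homeostasis: population CV^2 grows with added-size noise."""
    cv2_adds = cfg.sweep or [0.05, 0.5, 1.0]
    mean = 20.0 if cfg.target_mean == 100.0 else cfg.target_mean
    params, part = _partition_setup(cfg, mean)
    n_lin = cfg.scale(cfg.n_lineages) // 2
    n_col = cfg.scale(cfg.n_colonies) // 2
    rows = []
    for i, c in enumerate(cv2_adds):
        cyc = CycleModel(kind="adder", cv2_added=c, mean_added=1.0)
        ends = partitioning_endpoint_ensemble(
            params, part, cyc, n_lin, n_generations=2 * cfg.n_generations,
            seed=(cfg.seed, 2 * i),
        )
        sc = summary_stats(ends, n_boot=100, seed=cfg.seed)
        snaps = colony_ensemble(
            params, cyc, StopRule(generations=cfg.n_generations), n_colonies=n_col,
            partition=part, seed=(cfg.seed, 2 * i + 1), expression="deterministic",
        )
        pop = population_stats(snaps, seed=cfg.seed)
        for tag, s in (("single_cell", sc), ("population", pop)):
            rows.append(dict(cv2_added=c, perspective=tag, n=s.n, mean=s.mean,
                             cv2=s.cv2, se_cv2=s.se_cv2))
    return {"stats": pd.DataFrame(rows)}


EXPERIMENTS = {
    "feedback_sweep": feedback_sweep,
    "cycle_noise_sweep": cycle_noise_sweep,
    "mean_scaling": mean_scaling,
    "burst_vs_partition": burst_vs_partition,
    "divergence": divergence,
    "equivalence_checks": equivalence_checks,
    "degradation_sweep": degradation_sweep,
    "growth_coupled": growth_coupled,
    "adder": adder,
}


def run_experiment(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Run a named experiment; write TSV tables, the config and a log if out_dir set."""
    if cfg.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; "
            f"choose from {sorted(EXPERIMENTS)}"
        )
    t0 = time.time()
    tables = EXPERIMENTS[cfg.experiment](cfg)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{cfg.experiment}_{name}.tsv", sep="\t", index=False)
        cfg.to_yaml(out / f"{cfg.experiment}_config.yaml")
        log = dict(experiment=cfg.experiment, seed=cfg.seed,
                   runtime_s=round(time.time() - t0, 2),
                   tables={k: list(v.columns) for k, v in tables.items()})
        (out / f"{cfg.experiment}_log.json").write_text(json.dumps(log, indent=2))
    return tables
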