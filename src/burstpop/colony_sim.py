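"""Population-perspective agent-based colony simulator.

A colony expands from a single progenitor.  Within each cell the
concentration follows the same dynamics as in the lineage simulator
(bursts + feedback dilution, or the deterministic/bursty partitioning-model
dynamics); division is triggered either by the state-dependent hazard
``gamma/(1+k x)`` (exact thinning against the bound ``gamma``), by an i.i.d.
gamma timer, or by an adder size-control rule.  Both daughters are kept, and
a snapshot of every live cell is taken at exactly the stop time.

Because cells never interact after birth, the colony is expanded depth-first
(a stack of newborn cells), which is equivalent in law to a global
time-ordered event queue and considerably simpler.  Statistics over many
colonies use independently derived child random streams, so adding colonies
never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .estimators import SummaryStats, pooled_stats_with_bootstrap
from .model_core import (
    LN2,
    BurstFeedbackParams,
    BurstMode,
    CycleKind,
    CycleModel,
    DilutionMode,
    PartitionModel,
    as_generator,
    draw_partition,
    flow_map,
    spawn_generators,
)

__all__ = [
    "StopRule",
    "CellRecord",
    "ColonySnapshot",
    "PopulationGrowthEstimate",
    "simulate_colony",
    "colony_ensemble",
    "population_stats",
    "estimate_growth_rate",
    "export_lineage_newick",
]


@dataclass(frozen=True)
class StopRule:
    """Exactly one of ``time`` or ``generations`` must be set.

    ``generations = n`` stops at the fixed horizon ``n * <tau_d>`` (timer and
    adder modes) or ``n * ln2/gamma`` (hazard mode) — n population-doubling
    times, shared by every colony.  With a deterministic timer this horizon
    contains exactly ``n`` synchronous divisions, so the snapshot holds
    exactly ``2**n`` cells.
    """

    time: Optional[float] = None
    generations: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.time is None) == (self.generations is None):
            raise ValueError("set exactly one of time= or generations=")
        if self.time is not None and self.time <= 0:
            raise ValueError("stop time must be > 0")
        if self.generations is not None and self.generations < 1:
            raise ValueError("generations must be >= 1")

    def horizon(self, params: BurstFeedbackParams, cycle: CycleModel) -> float:
        if self.time is not None:
            return self.time
        if cycle.kind is CycleKind.HAZARD_FEEDBACK:
            return self.generations * LN2 / params.gamma
        if cycle.kind is CycleKind.ADDER:
            growth = cycle.growth_rate if cycle.growth_rate is not None else params.gamma
            return self.generations * LN2 / growth
        return self.generations * cycle.resolved_mean_tau(params.gamma)


@dataclass
class CellRecord:
    """Lineage-tree node: one cell's identity and life span."""

    cell_id: int
    parent_id: int
    birth_time: float
    division_time: Optional[float] = None  # None = alive at the snapshot


@dataclass
class ColonySnapshot:
    """All live cells of one colony at a fixed time.

    ``concentrations`` is the multiset of concentrations over live cells,
    advanced deterministically to exactly ``time``.  ``truncated`` flags that
    the per-colony cell cap was hit, in which case the snapshot is incomplete
    (never silent).  ``tree`` (optional) maps cell_id to :class:`CellRecord`.
    """

    time: float
    concentrations: np.ndarray
    cell_count: int
    seed: object = None
    truncated: bool = False
    tree: Optional[dict] = None
    volumes: Optional[np.ndarray] = None


@dataclass(frozen=True)
class PopulationGrowthEstimate:
    """Exponential growth rate fitted to pooled cell counts over time."""

    rate: float
    log_intercept: float
    n_colonies: int


def _next_division_time(
    params: BurstFeedbackParams,
    cycle: CycleModel,
    birth_time: float,
    x_birth: float,
    volume: float,
    rng: np.random.Generator,
    is_root: bool,
):
    """Division time for timer/adder cells (hazard cells divide via thinning)."""
    if cycle.kind is CycleKind.TIMER:
        tau = (
            cycle.draw_residual_cycle_time(params.gamma, rng)
            if is_root
            else cycle.draw_cycle_time(params.gamma, rng)
        )
        return birth_time + tau, volume
    if cycle.kind is CycleKind.ADDER:
        growth = cycle.growth_rate if cycle.growth_rate is not None else params.gamma
        added = cycle.draw_added_size(rng)
        tau = math.log1p(added / volume) / growth
        if is_root:
            # randomize the progenitor's cycle phase (uniform in time), so
            # colonies are not artificially synchronized at the snapshot
            tau *= rng.uniform(0.0, 1.0)
        return birth_time + tau, volume + added  # division size
    raise AssertionError


def simulate_colony(
    params: BurstFeedbackParams,
    cycle: CycleModel,
    stop: StopRule,
    partition: Optional[PartitionModel] = None,
    seed=None,
    x0: Optional[float] = None,
    expression: str = "bursty",
    track_tree: bool = False,
    max_cells: int = 2**16,
) -> ColonySnapshot:
    """Expand one colony from a single progenitor and snapshot it.

    Parameters
    ----------
    expression
        ``"bursty"``: bursts at rate ``lam`` (thinned in growth-coupled mode)
        with dilution/degradation flow in between — the feedback model.
        ``"deterministic"``: ``dx/dt = lam*beta - gamma*x`` — the
        partitioning model's noise-free synthesis.
    partition
        Partitioning kernel applied at division (default: perfect
        partitioning, daughters inherit the mother's concentration).
    x0
        Progenitor concentration; defaults to ``lam*beta/gamma``.
    max_cells
        Hard per-colony guard; exceeding it flags ``truncated`` on the
        snapshot rather than raising.
    """
    if expression not in ("bursty", "deterministic"):
        raise ValueError(f"unknown expression mode {expression!r}")
    rng = as_generator(seed)
    if partition is None:
        partition = PartitionModel(epsilon=0.0)
    if x0 is None:
        x0 = params.lam * params.beta / params.gamma
    T = stop.horizon(params, cycle)
    g, k, lam = params.gamma, params.k, params.lam
    xbar = lam * params.beta / g
    hazard_mode = cycle.kind is CycleKind.HAZARD_FEEDBACK
    coupled = params.burst_mode is BurstMode.GROWTH_COUPLED
    const_division = params.dilution_mode is DilutionMode.CONSTANT

    def flow(x: float, dt: float) -> float:
        if expression == "deterministic":
            return xbar + (x - xbar) * math.exp(-g * dt)
        return flow_map(x, dt, params)

    concentrations: list[float] = []
    volumes: list[float] = []
    tree: dict[int, CellRecord] = {}
    next_id = 0
    truncated = False
    # stack entries: (birth_time, x_birth, volume, cell_id, parent_id, is_root)
    stack = [(0.0, float(x0), cycle.mean_added, 0, -1, True)]
    next_id = 1
    while stack:
        tb, xb, vb, cid, pid, is_root = stack.pop()
        if track_tree:
            tree[cid] = CellRecord(cid, pid, tb)
        # determine this cell's division time (and division volume for adder)
        if hazard_mode:
            td, v_div = None, vb  # found on the fly by thinning
        else:
            td, v_div = _next_division_time(params, cycle, tb, xb, vb, rng, is_root)
        # simulate the cell's interior from tb
        t, x = tb, xb
        divided = False
        while True:
            if expression == "bursty" and lam > 0:
                t_burst = t + rng.exponential(1.0 / lam)
            else:
                t_burst = math.inf
            if hazard_mode:
                # thinning proposal at the constant bound gamma
                t_prop = t + rng.exponential(1.0 / g)
            else:
                t_prop = td
            t_next = min(t_burst, t_prop, T)
            x = flow(x, t_next - t)
            t = t_next
            if t == T and T <= min(t_burst, t_prop):
                break
            if t == t_burst and t_burst <= t_prop:
                if coupled and rng.random() >= 1.0 / (1.0 + k * x):
                    continue  # thinned-out burst candidate
                x += rng.exponential(params.beta)
                continue
            # division proposal
            if hazard_mode:
                accept = const_division or rng.random() < 1.0 / (1.0 + k * x)
                if not accept:
                    continue
            divided = True
            break
        if not divided:
            concentrations.append(x)
            volumes.append(vb * math.exp(g * (T - tb)) if cycle.kind is CycleKind.ADDER else vb)
            continue
        if track_tree:
            tree[cid].division_time = t
        if next_id + 1 >= max_cells:
            truncated = True
            concentrations.append(x)  # keep the mother so the pool is never empty
            continue
        x_plus = draw_partition(x, partition, rng) if x > 0 else x
        v_child = v_div / 2.0
        for xc in (x_plus, 2.0 * x - x_plus):
            stack.append((t, xc, v_child, next_id, cid, False))
            next_id += 1
    return ColonySnapshot(
        time=T,
        concentrations=np.asarray(concentrations),
        cell_count=len(concentrations),
        seed=seed,
        truncated=truncated,
        tree=tree if track_tree else None,
        volumes=np.asarray(volumes) if cycle.kind is CycleKind.ADDER else None,
    )


def colony_ensemble(
    params: BurstFeedbackParams,
    cycle: CycleModel,
    stop: StopRule,
    n_colonies: int,
    partition: Optional[PartitionModel] = None,
    seed=None,
    x0: Optional[float] = None,
    x0_sampler=None,
    expression: str = "bursty",
    track_tree: bool = False,
    max_cells: int = 2**16,
) -> list[ColonySnapshot]:
    """Simulate ``n_colonies`` independent colonies on derived child streams.

    ``x0_sampler(rng) -> float``, if given, draws each progenitor's initial
    concentration (e.g. from a warm-start distribution); otherwise ``x0``
    (or its default) is used for every colony.
    """
    rngs = spawn_generators(seed, n_colonies)
    out = []
    for r in rngs:
        start = x0_sampler(r) if x0_sampler is not None else x0
        out.append(
            simulate_colony(
                params, cycle, stop, partition=partition, seed=r, x0=start,
                expression=expression, track_tree=track_tree, max_cells=max_cells,
            )
        )
    return out


def population_stats(
    snapshots: Sequence[ColonySnapshot],
    n_boot: int = 200,
    seed=None,
) -> SummaryStats:
    """Pool all cells across colonies (equal per-cell weight) and summarize.

    Standard errors come from a bootstrap that resamples whole colonies,
    respecting the within-colony dependence of cell concentrations.
    """
    if len(snapshots) == 0:
        raise ValueError("need at least one snapshot")
    groups = [np.asarray(s.concentrations, dtype=float) for s in snapshots]
    if sum(g.size for g in groups) == 0:
        raise ValueError("empty cell pool")
    return pooled_stats_with_bootstrap(groups, n_boot=n_boot, seed=seed)


def estimate_growth_rate(
    snapshots: Sequence[ColonySnapshot],
    n_times: int = 20,
    skip_fraction: float = 0.25,
) -> PopulationGrowthEstimate:
    """Fit the exponential growth rate from pooled cell counts over time.

    Counts are reconstructed from the lineage trees (one extra cell per
    division); ``log N(t)`` is fitted by least squares on a uniform time grid
    after discarding the initial ``skip_fraction`` of the horizon.
    """
    div_times = []
    T = snapshots[0].time
    for s in snapshots:
        if s.tree is None:
            raise ValueError("growth-rate estimation needs snapshots with track_tree=True")
        div_times.extend(
            rec.division_time for rec in s.tree.values() if rec.division_time is not None
        )
    div_times = np.sort(np.asarray(div_times))
    tgrid = np.linspace(skip_fraction * T, T, n_times)
    counts = len(snapshots) + np.searchsorted(div_times, tgrid, side="right")
    slope, intercept = np.polyfit(tgrid, np.log(counts), 1)
    return PopulationGrowthEstimate(
        rate=float(slope), log_intercept=float(intercept), n_colonies=len(snapshots)
    )


def export_lineage_newick(snapshot: ColonySnapshot) -> str:
    """Serialize the colony's lineage tree as a newick string.

    Branch lengths are cell lifetimes (division time, or the snapshot time
    for live cells, minus birth time); leaf labels are ``c<cell_id>``.
    """
    if snapshot.tree is None:
        raise ValueError("snapshot carries no lineage tree (use track_tree=True)")
    children: dict[int, list[int]] = {}
    for rec in snapshot.tree.values():
        children.setdefault(rec.parent_id, []).append(rec.cell_id)
    for kids in children.values():
        kids.sort()

    def render(cid: int) -> str:
        rec = snapshot.tree[cid]
        end = rec.division_time if rec.division_time is not None else snapshot.time
        branch = end - rec.birth_time
        kids = children.get(cid, [])
        if kids:
            inner = ",".join(render(c) for c in kids)
            return f"({inner})c{cid}:{branch:.10g}"
        return f"c{cid}:{branch:.10g}"

    return render(0) + ";"
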