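"""Single-cell (lineage) perspective simulators.

Two processes are simulated along one randomly chosen root-to-leaf path of
the lineage tree:

* the burst-dilution-feedback model — bursts at rate ``lam`` (or thinned
  ``lam/(1+k x)``), deterministic feedback dilution in between; division
  leaves the concentration unchanged, so division events play no role in
  this perspective and are not generated;
* the partitioning model — deterministic (``dx/dt = lam*beta - gamma*x``) or
  bursty expression within a cell cycle, with the concentration reset through
  the partitioning kernel at each division, following one daughter chosen
  uniformly at random.

Both simulators are exact event-driven schemes; a fixed-step tau-leaping
integrator is provided as an optional cross-check for the feedback model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model_core import (
    BurstFeedbackParams,
    BurstMode,
    CycleKind,
    CycleModel,
    PartitionModel,
    as_generator,
    draw_partition,
    flow_map,
    spawn_generators,
)

__all__ = [
    "Trajectory",
    "simulate_lineage_feedback",
    "simulate_lineage_partitioning",
    "feedback_endpoint_ensemble",
    "partitioning_endpoint_ensemble",
    "time_average_stats",
]


@dataclass
class Trajectory:
    """One lineage's (time, concentration) series with its event log.

    ``times`` contains the requested sampling grid merged with all event
    times (the sampled series never interpolates across a jump).  Events are
    ``(time, kind)`` with kind ``"burst"`` or ``"division"``.  ``diverging``
    flags a trajectory that exceeded the divergence cap (possible in the
    regime where no single-cell stationary law exists); such trajectories are
    truncated, not raised as errors.
    """

    times: np.ndarray
    x: np.ndarray
    events: list = field(default_factory=list)
    seed: object = None
    diverging: bool = False

    def endpoint(self) -> float:
        return float(self.x[-1])

    def to_tsv(self, path) -> None:
        """Write tab-separated (time, concentration, event_flag) rows."""
        ev = {t: kind for t, kind in self.events}
        with open(path, "w") as fh:
            fh.write("time\tconcentration\tevent_flag\n")
            for t, v in zip(self.times, self.x):
                fh.write(f"{t:.10g}\t{v:.10g}\t{ev.get(float(t), '.')}\n")


class _Recorder:
    """Merges a uniform sampling grid with event times while simulating."""

    def __init__(self, grid: np.ndarray):
        self.grid = grid
        self.idx = 0
        self.times: list[float] = []
        self.values: list[float] = []

    def advance(self, t_from: float, t_to: float, x_from: float, params) -> None:
        """Record grid points in (t_from, t_to] given x(t_from)=x_from flows freely."""
        while self.idx < len(self.grid) and self.grid[self.idx] <= t_to:
            tg = float(self.grid[self.idx])
            self.times.append(tg)
            self.values.append(flow_map(x_from, tg - t_from, params))
            self.idx += 1

    def event(self, t: float, x: float) -> None:
        self.times.append(t)
        self.values.append(x)


def simulate_lineage_feedback(
    params: BurstFeedbackParams,
    t_end: float,
    seed=None,
    x0: float = 0.0,
    n_grid: int = 201,
    divergence_cap: float = 1e9,
    integrator: str = "exact",
    dt: Optional[float] = None,
) -> Trajectory:
    """Exact event-driven trajectory of the burst-dilution-feedback PDMP.

    Burst waiting times are exponential with rate ``lam`` in constant mode;
    in growth-coupled mode candidate times are proposed at the bound ``lam``
    and accepted with probability ``1/(1+k x(t))`` (exact thinning).  Burst
    increments are exponential with mean ``beta``; between events the
    concentration follows :func:`~burstpop.model_core.flow_map`.

    ``integrator="tau_leaping"`` instead advances a fixed step (default
    ``gamma*dt = 0.01``), drawing a Poisson number of bursts per step; it is
    approximate and intended as a cross-check of the exact scheme.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rng = as_generator(seed)
    grid = np.linspace(0.0, t_end, n_grid)
    if integrator == "tau_leaping":
        return _tau_leap(params, t_end, rng, x0, grid, divergence_cap, dt)
    if integrator != "exact":
        raise ValueError(f"unknown integrator {integrator!r}")

    rec = _Recorder(grid)
    events: list = []
    t, x = 0.0, float(x0)
    diverging = False
    lam = params.lam
    while True:
        if lam > 0:
            w = rng.exponential(1.0 / lam)
        else:
            w = math.inf
        t_next = t + w
        if t_next >= t_end:
            rec.advance(t, t_end, x, params)
            break
        x_at = flow_map(x, w, params)
        if params.burst_mode is BurstMode.GROWTH_COUPLED:
            # thinning: accept the candidate with probability lam(x)/lam
            if rng.random() >= 1.0 / (1.0 + params.k * x_at):
                rec.advance(t, t_next, x, params)
                t, x = t_next, x_at
                continue
        rec.advance(t, t_next, x, params)
        x = x_at + rng.exponential(params.beta)
        t = t_next
        events.append((t, "burst"))
        rec.event(t, x)
        if x > divergence_cap:
            diverging = True
            break
    return Trajectory(
        times=np.asarray(rec.times),
        x=np.asarray(rec.values),
        events=events,
        seed=seed,
        diverging=diverging,
    )


def _tau_leap(params, t_end, rng, x0, grid, cap, dt) -> Trajectory:
    if dt is None:
        dt = 0.01 / params.gamma
    n_steps = int(math.ceil(t_end / dt))
    times = [0.0]
    values = [float(x0)]
    x, t = float(x0), 0.0
    diverging = False
    for _ in range(n_steps):
        step = min(dt, t_end - t)
        rate = params.burst_rate(x)
        x = flow_map(x, step, params)
        n_bursts = rng.poisson(rate * step)
        if n_bursts:
            x += rng.gamma(n_bursts, params.beta)
        t += step
        times.append(t)
        values.append(x)
        if x > cap:
            diverging = True
            break
    return Trajectory(
        times=np.asarray(times), x=np.asarray(values), events=[], seed=None,
        diverging=diverging,
    )


def _endpoint_feedback(params, t_end, rng, x0, cap) -> float:
    """Endpoint-only exact simulation (no grid bookkeeping), for ensembles."""
    t, x = 0.0, float(x0)
    lam, beta, k = params.lam, params.beta, params.k
    coupled = params.burst_mode is BurstMode.GROWTH_COUPLED
    while True:
        w = rng.exponential(1.0 / lam) if lam > 0 else math.inf
        if t + w >= t_end:
            return flow_map(x, t_end - t, params)
        x = flow_map(x, w, params)
        t += w
        if coupled and rng.random() >= 1.0 / (1.0 + k * x):
            continue
        x += rng.exponential(beta)
        if x > cap:
            return x  # diverging; caller sees values above the cap


def feedback_endpoint_ensemble(
    params: BurstFeedbackParams,
    n_reps: int,
    t_end: float,
    seed=None,
    x0: float = 0.0,
    divergence_cap: float = 1e9,
) -> np.ndarray:
    """Endpoint concentrations of ``n_reps`` independent lineages at ``t_end``.

    Fixed-time ensemble protocol: statistics at a fixed late time
    across replicas, each replicate on its own derived random stream.
    """
    rngs = spawn_generators(seed, n_reps)
    return np.array(
        [_endpoint_feedback(params, t_end, r, x0, divergence_cap) for r in rngs]
    )


# ---------------------------------------------------------------------------
# Partitioning model
# ---------------------------------------------------------------------------


def _simulate_partition_lineage(
    params: BurstFeedbackParams,
    partition: PartitionModel,
    cycle: CycleModel,
    t_end: float,
    rng: np.random.Generator,
    x0: float,
    bursty: bool,
    rec: Optional[_Recorder],
    events: Optional[list],
):
    """Core loop shared by the trajectory and ensemble entry points.

    Within a cycle the concentration either relaxes deterministically toward
    ``lam*beta/gamma`` or undergoes bursts with exponential decay at rate
    ``gamma`` (no growth feedback in the partitioning model).  The cycle of
    the root cell starts from the equilibrium residual-life draw so the
    division phase is stationary from t = 0.
    """
    g = params.gamma
    xbar = params.lam * params.beta / g
    decay = BurstFeedbackParams(
        lam=0.0, beta=params.beta, gamma=g, k=0.0, dilution_mode="constant"
    )

    def advance(x: float, t0: float, t1: float) -> float:
        """Evolve concentration from t0 to t1 inside a cycle (no division)."""
        if not bursty:
            xv = xbar + (x - xbar) * math.exp(-g * (t1 - t0))
            if rec is not None:
                # deterministic relaxation toward xbar
                while rec.idx < len(rec.grid) and rec.grid[rec.idx] <= t1:
                    tg = float(rec.grid[rec.idx])
                    rec.times.append(tg)
                    rec.values.append(xbar + (x - xbar) * math.exp(-g * (tg - t0)))
                    rec.idx += 1
            return xv
        t, lam = t0, params.lam
        while True:
            w = rng.exponential(1.0 / lam) if lam > 0 else math.inf
            if t + w >= t1:
                if rec is not None:
                    rec.advance(t, t1, x, decay)
                return x * math.exp(-g * (t1 - t))
            if rec is not None:
                rec.advance(t, t + w, x, decay)
            x = x * math.exp(-g * w) + rng.exponential(params.beta)
            t += w
            if events is not None:
                events.append((t, "burst"))
            if rec is not None:
                rec.event(t, x)

    if cycle.kind is CycleKind.ADDER:
        growth = cycle.growth_rate if cycle.growth_rate is not None else g
        volume = cycle.mean_added  # stationary newborn size for the adder
    t = 0.0
    x = float(x0)
    first = True
    while True:
        if cycle.kind is CycleKind.TIMER:
            tau = (
                cycle.draw_residual_cycle_time(g, rng)
                if first
                else cycle.draw_cycle_time(g, rng)
            )
        elif cycle.kind is CycleKind.ADDER:
            added = cycle.draw_added_size(rng)
            tau = math.log1p(added / volume) / growth
            if first:
                tau *= rng.uniform(0.0, 1.0)  # random initial cycle phase
            volume = (volume + added) / 2.0  # the followed daughter's birth size
        else:
            raise ValueError("partitioning lineage needs a timer or adder cycle")
        first = False
        if t + tau >= t_end:
            return advance(x, t, t_end)
        x = advance(x, t, t + tau)
        t += tau
        x_plus = draw_partition(x, partition, rng) if x > 0 else x
        # follow one daughter uniformly at random
        x = x_plus if rng.random() < 0.5 else 2.0 * x - x_plus
        if events is not None:
            events.append((t, "division"))
        if rec is not None:
            rec.event(t, x)


def simulate_lineage_partitioning(
    params: BurstFeedbackParams,
    partition: PartitionModel,
    cycle: CycleModel,
    n_generations: int,
    seed=None,
    x0: Optional[float] = None,
    bursty: bool = False,
    n_grid: int = 201,
) -> Trajectory:
    """Division-reset trajectory of the partitioning model along one lineage.

    Simulates for ``n_generations`` mean cycle times; at each division the
    concentration jumps through the partitioning kernel and one daughter is
    followed (uniformly at random).  ``x0`` defaults to the deterministic
    fixed point ``lam*beta/gamma``.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = as_generator(seed)
    if x0 is None:
        x0 = params.lam * params.beta / params.gamma
    t_end = n_generations * cycle.resolved_mean_tau(params.gamma)
    grid = np.linspace(0.0, t_end, n_grid)
    rec = _Recorder(grid)
    events: list = []
    x_final = _simulate_partition_lineage(
        params, partition, cycle, t_end, rng, x0, bursty, rec, events
    )
    if not rec.times or rec.times[-1] < t_end:
        rec.event(t_end, x_final)
    return Trajectory(
        times=np.asarray(rec.times), x=np.asarray(rec.values), events=events, seed=seed
    )


def partitioning_endpoint_ensemble(
    params: BurstFeedbackParams,
    partition: PartitionModel,
    cycle: CycleModel,
    n_reps: int,
    n_generations: int = 6,
    seed=None,
    x0: Optional[float] = None,
    bursty: bool = False,
) -> np.ndarray:
    """Endpoint concentrations of ``n_reps`` independent partitioning lineages."""
    if x0 is None:
        x0 = params.lam * params.beta / params.gamma
    t_end = n_generations * cycle.resolved_mean_tau(params.gamma)
    rngs = spawn_generators(seed, n_reps)
    return np.array(
        [
            _simulate_partition_lineage(
                params, partition, cycle, t_end, r, x0, bursty, None, None
            )
            for r in rngs
        ]
    )


def time_average_stats(traj: Trajectory, t_start: float = 0.0):
    """Time-averaged mean/CV^2/skewness over a trajectory (ergodic cross-check).

    Piecewise-constant weighting between recorded points; returns a
    ``(mean, cv2, skew)`` tuple.  Use a dense sampling grid for accuracy.
    """
    mask = traj.times >= t_start
    t = traj.times[mask]
    v = traj.x[mask]
    if t.size < 3:
        raise ValueError("trajectory too short for time averaging")
    w = np.diff(t)
    vals = v[:-1]
    wsum = w.sum()
    m1 = float((w * vals).sum() / wsum)
    m2 = float((w * vals**2).sum() / wsum)
    m3 = float((w * vals**3).sum() / wsum)
    var = m2 - m1**2
    skew = 0.0 if var == 0 else (m3 - 3 * m1 * var - m1**3) / var**1.5
    return m1, (0.0 if m1 == 0 else var / m1**2), skew
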