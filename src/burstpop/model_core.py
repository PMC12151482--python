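"""Shared mechanics of the burst-dilution gene-expression model.

The protein concentration ``x`` in a growing cell is a piecewise-deterministic
Markov process: instantaneous synthesis *bursts* (exponentially distributed
sizes, mean ``beta``) arriving at frequency ``lambda``, interleaved with a
deterministic dilution flow.  High concentration can slow growth — and hence
dilution and division — through the Hill-like factor ``1/(1 + k*x)``, which
implements an effective positive feedback on concentration.

This module holds the parameter containers, the dilution flow solution, the
random partitioning kernel applied at cytokinesis, the state-dependent
division hazard, and the cell-cycle-time machinery used by both the lineage
(single-cell) and colony (population) simulators.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LN2",
    "BurstMode",
    "DilutionMode",
    "PartitionKernel",
    "CycleKind",
    "BurstFeedbackParams",
    "PartitionModel",
    "CycleModel",
    "CellState",
    "flow_map",
    "draw_partition",
    "division_hazard",
    "calibrate_cycle_mean",
    "default_cycle_mean",
    "as_generator",
    "spawn_generators",
]

LN2 = math.log(2.0)

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


def as_generator(seed: SeedLike) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_generators(seed: SeedLike, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child random streams from one parent seed.

    Replicates simulated from sibling streams are statistically independent,
    and adding replicates never perturbs the streams of earlier ones.
    """
    if isinstance(seed, np.random.Generator):
        return seed.spawn(n)
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in seed.spawn(n)]


class BurstMode(str, enum.Enum):
    """How the burst frequency depends on the cell state.

    ``CONSTANT``: bursts arrive at fixed rate ``lam``.
    ``GROWTH_COUPLED``: the burst rate scales with the growth rate,
    ``lam / (1 + k*x)`` — synthesis slows together with growth.
    """

    CONSTANT = "constant"
    GROWTH_COUPLED = "growth_coupled"


class DilutionMode(str, enum.Enum):
    """``FEEDBACK``: dilution/division rate ``gamma/(1+k*x)``; ``CONSTANT``: ``gamma``."""

    FEEDBACK = "feedback"
    CONSTANT = "constant"


class PartitionKernel(str, enum.Enum):
    PERFECT = "perfect"
    BETA_MATCHED = "beta_matched"
    BINOMIAL_DISCRETIZED = "binomial_discretized"


class CycleKind(str, enum.Enum):
    HAZARD_FEEDBACK = "hazard_feedback"
    TIMER = "timer"
    ADDER = "adder"


@dataclass(frozen=True)
class BurstFeedbackParams:
    """Full parameterization of the burst-dilution-feedback model.

    Parameters
    ----------
    lam
        Burst frequency (events per unit time), >= 0.
    beta
        Mean burst size (concentration units), > 0.
    gamma
        Maximum dilution rate (per unit time), > 0.  All times in the package
        are expressed in units of this model time; there is no wall-clock
        semantics.
    k
        Feedback strength (per concentration unit), >= 0.  ``k = 0`` recovers
        the unregulated model with constant dilution ``gamma``.
    d
        Constant first-order degradation rate on top of dilution, >= 0
        (default 0: a stable protein whose decay is dilution only).
    burst_mode, dilution_mode
        See :class:`BurstMode` and :class:`DilutionMode`.
    """

    lam: float
    beta: float
    gamma: float
    k: float = 0.0
    d: float = 0.0
    burst_mode: BurstMode = BurstMode.CONSTANT
    dilution_mode: DilutionMode = DilutionMode.FEEDBACK

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"burst frequency lam must be >= 0, got {self.lam}")
        if self.beta <= 0:
            raise ValueError(f"mean burst size beta must be > 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"max dilution rate gamma must be > 0, got {self.gamma}")
        if self.k < 0:
            raise ValueError(f"feedback strength k must be >= 0, got {self.k}")
        if self.d < 0:
            raise ValueError(f"degradation rate d must be >= 0, got {self.d}")
        object.__setattr__(self, "burst_mode", BurstMode(self.burst_mode))
        object.__setattr__(self, "dilution_mode", DilutionMode(self.dilution_mode))

    def burst_rate(self, x: float) -> float:
        """Instantaneous burst propensity at concentration ``x``."""
        if self.burst_mode is BurstMode.GROWTH_COUPLED:
            return self.lam / (1.0 + self.k * x)
        return self.lam

    def growth_rate(self, x: float) -> float:
        """Cellular growth (= dilution = division) rate at concentration ``x``."""
        if self.dilution_mode is DilutionMode.FEEDBACK:
            return self.gamma / (1.0 + self.k * x)
        return self.gamma


@dataclass(frozen=True)
class PartitionModel:
    """Randomness of molecule segregation between daughters at division.

    A mother at concentration ``x`` produces daughters ``x+`` and ``2x - x+``
    where ``x+`` has conditional mean ``x``, conditional variance
    ``epsilon * x`` and support ``(0, 2x)`` — the continuous analogue of
    binomial molecule partitioning.  ``epsilon = 0`` is perfect partitioning
    (``x+ = x`` with probability one).
    """

    epsilon: float = 0.0
    kernel: PartitionKernel = PartitionKernel.BETA_MATCHED

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        object.__setattr__(self, "kernel", PartitionKernel(self.kernel))
        if self.epsilon == 0:
            # zero variance forces the perfect kernel
            object.__setattr__(self, "kernel", PartitionKernel.PERFECT)


@dataclass(frozen=True)
class CycleModel:
    """Cell-division timing mechanism.

    ``HAZARD_FEEDBACK``
        Division is a point process with state-dependent rate
        ``gamma / (1 + k*x)`` (the growth rate); no timer parameters needed.
    ``TIMER``
        Cycle durations are i.i.d. gamma with mean ``mean_tau`` and squared
        coefficient of variation ``cv2_tau`` (``cv2_tau = 0`` is a
        deterministic timer).  If ``mean_tau`` is None the simulators default
        it to the volume-doubling time ``ln2/gamma`` (see
        :func:`default_cycle_mean`).
    ``ADDER``
        Cell volume grows exponentially at ``growth_rate`` and the cell
        divides once it has added a random volume increment since birth
        (gamma-distributed, mean ``mean_added``, squared CV ``cv2_added``).
        Added size is independent of newborn size, giving size homeostasis.
    """

    kind: CycleKind = CycleKind.TIMER
    cv2_tau: float = 0.0
    mean_tau: Optional[float] = None
    mean_added: float = 1.0
    cv2_added: float = 0.0
    growth_rate: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CycleKind(self.kind))
        if self.cv2_tau < 0:
            raise ValueError(f"cv2_tau must be >= 0, got {self.cv2_tau}")
        if self.mean_tau is not None and self.mean_tau <= 0:
            raise ValueError(f"mean_tau must be > 0, got {self.mean_tau}")
        if self.kind is CycleKind.ADDER:
            if self.mean_added <= 0:
                raise ValueError("mean_added must be > 0 in adder mode")
            if self.cv2_added < 0:
                raise ValueError("cv2_added must be >= 0 in adder mode")

    # -- timer draws ---------------------------------------------------------

    def resolved_mean_tau(self, gamma: float) -> float:
        return self.mean_tau if self.mean_tau is not None else default_cycle_mean(gamma)

    def draw_cycle_time(self, gamma: float, rng: np.random.Generator) -> float:
        """One i.i.d. timer cycle duration."""
        m = self.resolved_mean_tau(gamma)
        if self.cv2_tau == 0.0:
            return m
        a = 1.0 / self.cv2_tau
        return float(rng.gamma(a, m / a))

    def draw_residual_cycle_time(self, gamma: float, rng: np.random.Generator) -> float:
        """Equilibrium residual-life draw for a lineage/colony root.

        Starting the first cycle from the renewal-equilibrium residual
        distribution (density ``(1-F(a))/<tau>``) makes the division phase of
        the process time-stationary from t=0.  Sampled via the standard
        size-bias trick: draw tau* with density ``tau f(tau)/<tau>`` — for a
        gamma law, gamma with shape ``a+1`` — and return ``U * tau*``.
        """
        m = self.resolved_mean_tau(gamma)
        if self.cv2_tau == 0.0:
            tau_star = m
        else:
            a = 1.0 / self.cv2_tau
            tau_star = float(rng.gamma(a + 1.0, m / a))
        return float(rng.uniform(0.0, tau_star))

    def draw_added_size(self, rng: np.random.Generator) -> float:
        if self.cv2_added == 0.0:
            return self.mean_added
        a = 1.0 / self.cv2_added
        return float(rng.gamma(a, self.mean_added / a))


@dataclass
class CellState:
    """State of one cell in an agent-based colony simulation."""

    x: float
    age: float = 0.0
    birth_time: float = 0.0
    volume: float = 1.0
    cell_id: int = 0
    parent_id: int = -1

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("concentration must be >= 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")


# ---------------------------------------------------------------------------
# Deterministic dilution flow
# ---------------------------------------------------------------------------


def _lambert_exp(y: float) -> float:
    """Solve ``w + log(w) = y`` for ``w > 0`` (i.e. ``w = W(exp(y))``).

    Working with the log form avoids overflow of exp(y) for large y.  Newton
    iteration; the function is smooth and strictly increasing so convergence
    is quadratic from the starting points below.
    """
    w = y if y > 1.0 else math.exp(min(y, 1.0))
    for _ in range(100):
        dw = (w + math.log(w) - y) * w / (w + 1.0)
        w -= dw
        if w <= 0.0:  # overshoot guard (only possible far from the root)
            w = 1e-300
        if abs(dw) <= 1e-14 * max(w, 1.0):
            return w
    return w


def flow_map(x0: float, t: float, params: BurstFeedbackParams) -> float:
    """Concentration after deterministic dilution/degradation for time ``t``.

    Solves ``dx/dt = -gamma x/(1+k x) - d x`` (feedback dilution mode) or
    ``dx/dt = -(gamma+d) x`` (constant dilution mode) from ``x(0) = x0``.

    For ``d = 0`` the feedback flow has the implicit solution
    ``log x + k x = log x0 + k x0 - gamma t``, inverted through the principal
    Lambert-W branch.  For ``d > 0`` the exact conserved quantity
    ``log x + (gamma/d) log(gamma + d + d k x) = const - (gamma+d) t``
    is inverted by bracketed root finding.
    """
    if x0 < 0:
        raise ValueError(f"x0 must be >= 0, got {x0}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if x0 == 0.0 or t == 0.0:
        return float(x0)
    g, k, d = params.gamma, params.k, params.d
    if params.dilution_mode is DilutionMode.CONSTANT or k == 0.0:
        return float(x0 * math.exp(-(g + d) * t))
    if d == 0.0:
        # k x * exp(k x) = k x0 * exp(k x0 - gamma t)
        y = math.log(k * x0) + k * x0 - g * t
        return _lambert_exp(y) / k
    c = g + d

    def F(x: float) -> float:
        return math.log(x) + (g / d) * math.log(c + d * k * x)

    target = F(x0) - c * t
    lo = x0 * math.exp(-c * t) * 0.5  # decay is at most rate c, at least ~gamma
    while F(lo) > target:
        lo *= 0.5
    return float(brentq(lambda x: F(x) - target, lo, x0, xtol=1e-15, rtol=8.9e-16))


def flow_map_array(x0: np.ndarray, t: float, params: BurstFeedbackParams) -> np.ndarray:
    """Vectorized :func:`flow_map` over an array of initial concentrations."""
    x0 = np.asarray(x0, dtype=float)
    g, k, d = params.gamma, params.k, params.d
    if params.dilution_mode is DilutionMode.CONSTANT or k == 0.0:
        return x0 * math.exp(-(g + d) * t)
    return np.array([flow_map(v, t, params) for v in x0.ravel()]).reshape(x0.shape)


# ---------------------------------------------------------------------------
# Partitioning kernel
# ---------------------------------------------------------------------------


def draw_partition(
    x: float, model: PartitionModel, rng: np.random.Generator
) -> float:
    """Draw the concentration ``x+`` inherited by one daughter.

    Conditional mean ``x``, conditional variance ``epsilon*x`` (when the
    kernel can realize it), support strictly inside ``(0, 2x)``.  The
    complementary daughter receives ``2x - x+``.

    The default ``beta_matched`` kernel is a symmetric beta on ``(0, 2x)``
    with shape ``a = (x/epsilon - 1)/2``, which matches both prescribed
    conditional moments exactly; it is feasible only for ``x > epsilon``.
    For ``x <= epsilon`` the kernel falls back to ``binomial_discretized``:
    ``m ~ Binomial(n, 1/2)`` effective molecules with ``n = round(x/epsilon)``
    (at least 3; ``Var(2x m/n) = x**2/n``, so this n reproduces ``epsilon*x``),
    returning ``2x*m/n`` and rejecting the boundary outcomes
    ``m in {0, n}`` to keep the support open.  For ``x <= epsilon`` the target
    variance ``epsilon*x >= x**2`` is infeasible on an open ``(0, 2x)``
    support, so the realized variance there is necessarily smaller — the
    fallback delivers the closest binomial analogue rather than silently
    wrong moments elsewhere.
    """
    if x <= 0:
        raise ValueError(f"x must be > 0 to partition, got {x}")
    eps = model.epsilon
    if model.kernel is PartitionKernel.PERFECT or eps == 0.0:
        return float(x)
    if model.kernel is PartitionKernel.BETA_MATCHED and x > eps:
        a = (x / eps - 1.0) / 2.0
        for _ in range(100):
            b = rng.beta(a, a)
            if 0.0 < b < 1.0:
                return float(2.0 * x * b)
        raise RuntimeError("beta kernel failed to produce an interior draw")
    # binomial fallback (also the explicit binomial_discretized kernel)
    n = max(3, int(round(x / eps)))
    for _ in range(1000):
        m = int(rng.binomial(n, 0.5))
        if 0 < m < n:
            return float(2.0 * x * m / n)
    raise RuntimeError("binomial kernel failed to produce an interior draw")


# ---------------------------------------------------------------------------
# Division hazard and cycle-time calibration
# ---------------------------------------------------------------------------


def division_hazard(x: float, params: BurstFeedbackParams) -> float:
    """State-dependent division rate ``gamma/(1+k x)`` (or ``gamma`` without feedback).

    Monotone non-increasing in ``x`` and bounded above by ``gamma``, which is
    what makes exact thinning against the constant bound ``gamma`` possible in
    the colony simulator.
    """
    if x < 0:
        raise ValueError(f"x must be >= 0, got {x}")
    return params.growth_rate(x)


def calibrate_cycle_mean(cv2_tau: float, gamma: float) -> float:
    """Mean gamma-distributed cycle time satisfying the Euler-Lotka relation.

    Returns ``<tau_d>`` such that a binary-splitting population with i.i.d.
    gamma cycle times (squared CV ``cv2_tau``) grows exactly at rate
    ``gamma`` — i.e. ``2 E[exp(-gamma tau_d)] = 1`` (doubling time
    ``ln2/gamma``).  For shape ``a = 1/cv2_tau`` the closed form is
    ``<tau_d> = a (2**(1/a) - 1)/gamma``; a deterministic timer
    (``cv2_tau = 0``) gives ``ln2/gamma``.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if cv2_tau < 0:
        raise ValueError(f"cv2_tau must be >= 0, got {cv2_tau}")
    if cv2_tau == 0.0:
        return LN2 / gamma
    a = 1.0 / cv2_tau
    return a * (2.0 ** (1.0 / a) - 1.0) / gamma


def default_cycle_mean(gamma: float) -> float:
    """Volume-doubling time ``ln2/gamma`` — the package's timer-mean convention.

    A cell whose volume grows exponentially at the dilution rate ``gamma``
    doubles in ``ln2/gamma``; fixing the mean cycle time to this value for
    every ``cv2_tau`` keeps the single-cell dilution picture consistent with
    discrete doubling, and it is the convention under which the single-cell
    partitioning noise ``epsilon/(2 ln2 x_bar)`` is invariant to cycle-time
    randomness.  (:func:`calibrate_cycle_mean` instead fixes the *population*
    growth rate at ``gamma``; the two coincide for a deterministic timer.)
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    return LN2 / gamma
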