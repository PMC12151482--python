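"""Ensemble summary statistics and perspective-comparison utilities.

Conventions (fixed across the package): the variance uses the divisor-n
(population-moment) form, since the CV^2 reported throughout is a property
of a distribution estimated from large ensembles; skewness is the third
central moment over the 3/2 power of the second; degenerate samples have
CV^2 = 0 and skewness 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np
from scipy import stats as sps

from .model_core import as_generator

__all__ = [
    "SummaryStats",
    "PerspectiveComparison",
    "summary_stats",
    "pooled_stats_with_bootstrap",
    "ks_distance",
    "compare_perspectives",
    "write_stats_table",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, CV^2 and skewness of an ensemble, with bootstrap standard errors."""

    n: int
    mean: float
    cv2: float
    skew: float
    se_mean: float = float("nan")
    se_cv2: float = float("nan")
    se_skew: float = float("nan")
    convention: str = "population-moments"


def _raw_stats(x: np.ndarray) -> tuple[float, float, float]:
    m = float(x.mean())
    var = float(x.var())  # divisor n
    # degenerate up to floating-point rounding of identical values
    if var <= (16.0 * np.finfo(float).eps * max(abs(m), 1.0)) ** 2:
        return m, 0.0, 0.0
    if m == 0.0:
        raise ValueError("CV^2 undefined: zero mean with nonzero variance")
    m3 = float(((x - m) ** 3).mean())
    return m, var / m**2, m3 / var**1.5


def summary_stats(samples, n_boot: int = 0, seed=None) -> SummaryStats:
    """Summarize an i.i.d. ensemble of concentrations.

    ``n_boot > 0`` adds bootstrap standard errors (i.i.d. resampling; for
    colony-structured data use :func:`pooled_stats_with_bootstrap` /
    ``population_stats``, which resample whole colonies instead).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    mean, cv2, skew = _raw_stats(x)
    se = (float("nan"),) * 3
    if n_boot > 0 and x.size > 1:
        rng = as_generator(seed)
        reps = np.empty((n_boot, 3))
        for b in range(n_boot):
            xb = x[rng.integers(0, x.size, x.size)]
            reps[b] = _raw_stats(xb)
        se = tuple(reps.std(axis=0, ddof=1))
    return SummaryStats(
        n=x.size, mean=mean, cv2=cv2, skew=skew,
        se_mean=se[0], se_cv2=se[1], se_skew=se[2],
    )


def pooled_stats_with_bootstrap(
    groups: Sequence[np.ndarray], n_boot: int = 200, seed=None
) -> SummaryStats:
    """Equal-per-cell pooled statistics with group-level (colony) bootstrap."""
    groups = [np.asarray(grp, dtype=float) for grp in groups if len(grp)]
    pooled = np.concatenate(groups)
    mean, cv2, skew = _raw_stats(pooled)
    se = (float("nan"),) * 3
    if n_boot > 0 and len(groups) > 1:
        rng = as_generator(seed)
        reps = np.empty((n_boot, 3))
        for b in range(n_boot):
            idx = rng.integers(0, len(groups), len(groups))
            reps[b] = _raw_stats(np.concatenate([groups[i] for i in idx]))
        se = tuple(reps.std(axis=0, ddof=1))
    return SummaryStats(
        n=pooled.size, mean=mean, cv2=cv2, skew=skew,
        se_mean=se[0], se_cv2=se[1], se_skew=se[2],
    )


def ks_distance(samples, law: Union[Callable[[np.ndarray], np.ndarray], object]) -> float:
    """Kolmogorov-Smirnov sup-distance between an ensemble and a reference law.

    ``law`` is either a stationary-law object exposing ``.cdf`` (e.g.
    :class:`~burstpop.analytics.StationaryLaw`) or a cdf callable.  Passing
    the same empirical sample against its own edf gives 0.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for a KS distance")
    cdf = law.cdf if hasattr(law, "cdf") else law
    probe = cdf(np.asarray([0.0, 1.0]))
    if not np.all(np.isfinite(probe)):
        raise ValueError("reference law has no finite cdf (not normalizable)")
    return float(sps.ks_1samp(x, cdf).statistic)


@dataclass(frozen=True)
class PerspectiveComparison:
    """Population/single-cell ratios of the three summary statistics.

    ``pop_noisier`` flags a population CV^2 significantly above the
    single-cell one (ratio more than two propagated SEs above 1).
    """

    ratio_mean: float
    ratio_cv2: float
    ratio_skew: float
    se_ratio_mean: float
    se_ratio_cv2: float
    se_ratio_skew: float
    pop_noisier: bool


def _ratio_and_se(num, se_num, den, se_den) -> tuple[float, float]:
    r = num / den
    rel = 0.0
    for v, s in ((num, se_num), (den, se_den)):
        if np.isfinite(s) and v != 0:
            rel += (s / v) ** 2
    return r, abs(r) * np.sqrt(rel)


def compare_perspectives(sc: SummaryStats, pop: SummaryStats) -> PerspectiveComparison:
    """Ratios (population over single-cell) with delta-method error propagation."""
    rm, sm = _ratio_and_se(pop.mean, pop.se_mean, sc.mean, sc.se_mean)
    rc, scv = _ratio_and_se(pop.cv2, pop.se_cv2, sc.cv2, sc.se_cv2)
    rs, ss = _ratio_and_se(pop.skew, pop.se_skew, sc.skew, sc.se_skew)
    noisier = bool(np.isfinite(scv) and (rc - 1.0) > 2.0 * scv)
    return PerspectiveComparison(
        ratio_mean=rm, ratio_cv2=rc, ratio_skew=rs,
        se_ratio_mean=sm, se_ratio_cv2=scv, se_ratio_skew=ss,
        pop_noisier=noisier,
    )


def write_stats_table(rows: Sequence[dict], path) -> None:
    """Write (condition, perspective, n, mean, cv2, skew, se_*) rows as TSV."""
    import pandas as pd

    cols = ["condition", "perspective", "n", "mean", "cv2", "skew",
            "se_mean", "se_cv2", "se_skew"]
    df = pd.DataFrame(list(rows))
    df = df[[c for c in cols if c in df.columns]
            + [c for c in df.columns if c not in cols]]
    df.to_csv(path, sep="\t", index=False)
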