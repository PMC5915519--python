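"""Survival and group-comparison statistics, implemented from first principles.

Kaplan–Meier product-limit estimation, the two-group log-rank test and a
Dunnett-style many-to-one multiple comparison are the core inferential tools
of a preclinical efficacy study: animals reach a composite endpoint (tumor
burden or excessive weight loss) or are censored, and each treated group is
compared against the shared control.

These estimators are authored here rather than delegated so their
conventions (tie handling, censoring order, Monte-Carlo adjustment) are
explicit; established survival packages serve as independent cross-checks in
the test suite only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EndpointEvent",
    "SurvivalCurve",
    "LogrankResult",
    "DunnettResult",
    "kaplan_meier",
    "logrank",
    "dunnett_many_to_one",
]


@dataclass(frozen=True)
class EndpointEvent:
    """One subject's endpoint outcome: event or censoring at ``day``."""

    animal_id: str
    day: float
    status: str  # "event" | "censored"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        if self.status not in ("event", "censored"):
            raise ValueError(f"status must be 'event' or 'censored', got {self.status!r}")


@dataclass
class SurvivalCurve:
    """Step-function survival estimate.

    ``times`` are the distinct observation times in increasing order;
    ``survival[i]`` is Ŝ(t) for t in [times[i], times[i+1]); Ŝ = 1 before
    the first time.  ``at_risk`` and ``events`` record nᵢ and dᵢ at each
    time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Ŝ(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def _as_arrays(events: Iterable[EndpointEvent]) -> tuple[np.ndarray, np.ndarray]:
    evs = list(events)
    if not evs:
        raise ValueError("empty event list")
    days = np.array([e.day for e in evs], dtype=float)
    observed = np.array([e.status == "event" for e in evs], dtype=bool)
    return days, observed


def kaplan_meier(events: Iterable[EndpointEvent]) -> SurvivalCurve:
    """Product-limit survival estimate Ŝ(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ).

    Ties between events and censorings at the same time follow the standard
    convention: events are processed first, so subjects censored at tᵢ still
    count as at risk for the events at tᵢ.
    """
    days, observed = _as_arrays(events)
    times = np.unique(days)
    n_total = days.size
    at_risk = np.empty(times.size, dtype=int)
    d = np.empty(times.size, dtype=int)
    surv = np.empty(times.size, dtype=float)
    s = 1.0
    for i, t in enumerate(times):
        n_i = int(np.sum(days >= t))
        d_i = int(np.sum(observed & (days == t)))
        if n_i > 0 and d_i > 0:
            s *= 1.0 - d_i / n_i
        at_risk[i] = n_i
        d[i] = d_i
        surv[i] = s
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk, events=d)


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    observed_a: float
    expected_a: float
    variance: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.chi_square)


def logrank(
    group_a: Iterable[EndpointEvent], group_b: Iterable[EndpointEvent]
) -> LogrankResult:
    """Two-group log-rank test.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk sets;
    χ² = (ΣO − ΣE)² / ΣV is referred to χ²(1).  Groups with no events at all
    yield an undefined statistic (NaN) rather than an arbitrary value.
    """
    days_a, obs_a = _as_arrays(group_a)
    days_b, obs_b = _as_arrays(group_b)
    event_times = np.unique(np.concatenate([days_a[obs_a], days_b[obs_b]]))
    if event_times.size == 0:
        return LogrankResult(math.nan, math.nan, 0.0, 0.0, 0.0)

    O = E = V = 0.0
    for t in event_times:
        n1 = int(np.sum(days_a >= t))
        n2 = int(np.sum(days_b >= t))
        d1 = int(np.sum(obs_a & (days_a == t)))
        d2 = int(np.sum(obs_b & (days_b == t)))
        n = n1 + n2
        dt = d1 + d2
        if n == 0 or dt == 0:
            continue
        O += d1
        E += dt * n1 / n
        if n > 1:
            V += dt * (n1 / n) * (n2 / n) * (n - dt) / (n - 1)
    if V == 0.0:
        # no information (e.g. all events in a single risk set of size 1)
        return LogrankResult(math.nan, math.nan, O, E, V)
    chi = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi, df=1))
    return LogrankResult(chi, p, O, E, V)


@dataclass
class DunnettResult:
    """Many-to-one comparison of treatment groups against a shared control."""

    t_statistics: np.ndarray
    p_adjusted: np.ndarray
    p_unadjusted: np.ndarray
    df: int
    mc_draws: int


def dunnett_many_to_one(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    alpha: float = 0.05,
    mc_draws: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> DunnettResult:
    """Dunnett-style two-sided many-to-one comparison.

    Pooled-variance t statistics of each treatment mean against the control
    mean, with family-wise adjustment from a seeded Monte-Carlo sample of the
    max-|t| null distribution (equal means, homoscedastic normal errors).
    Adjusted p-values are floored at the unadjusted two-sided t p-value, the
    analytic lower bound of the Dunnett adjustment.

    ``alpha`` is carried for reporting; the returned p-values are the object
    of interest.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatments]
    if x0.size < 2 or any(g.size < 2 for g in groups) or not groups:
        raise ValueError("need >= 2 observations in control and every treatment group")

    k = len(groups)
    ns = np.array([g.size for g in groups])
    n0 = x0.size
    n_total = n0 + int(ns.sum())
    df = n_total - (k + 1)
    sse = float(np.sum((x0 - x0.mean()) ** 2)) + sum(
        float(np.sum((g - g.mean()) ** 2)) for g in groups
    )
    if sse <= 0 or df <= 0:
        raise ValueError("degenerate data: zero pooled variance or no residual df")
    mse = sse / df

    means = np.array([g.mean() for g in groups])
    se = np.sqrt(mse * (1.0 / ns + 1.0 / n0))
    t_obs = (means - x0.mean()) / se
    p_unadj = 2.0 * stats.t.sf(np.abs(t_obs), df)

    # Null max-|t|: group means under H0 differ only by noise; the shared
    # control mean induces the Dunnett correlation structure.
    z0 = rng.standard_normal(mc_draws) / math.sqrt(n0)
    zi = rng.standard_normal((mc_draws, k)) / np.sqrt(ns)
    s2 = rng.chisquare(df, size=mc_draws) / df
    t_null = (zi - z0[:, None]) / (np.sqrt(s2)[:, None] * np.sqrt(1.0 / ns + 1.0 / n0))
    max_abs_t = np.abs(t_null).max(axis=1)

    exceed = (max_abs_t[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
    p_adj = (exceed + 1.0) / (mc_draws + 1.0)
    p_adj = np.minimum(1.0, np.maximum(p_adj, p_unadj))

    return DunnettResult(
        t_statistics=t_obs,
        p_adjusted=p_adj,
        p_unadjusted=p_unadj,
        df=df,
        mc_draws=mc_draws,
    )
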