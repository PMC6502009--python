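"""Net failure at fixed horizons from right-censored revision times.

Net failure is 1 minus the Kaplan-Meier survival function for revision,
treating death as non-informative censoring: the probability of revision in
a hypothetical world without death.  Uncertainty comes from the Greenwood
variance of the product-limit estimate; single-construct reporting
intervals use the complementary log-log transform, which keeps the interval
inside [0, 1] and reproduces the asymmetry expected for failure
probabilities near zero.

Conventions (all deterministic and order-independent):

* Tied times are processed as one risk-set step; censorings recorded at an
  event time leave the risk set *after* the events at that time.
* The risk set at ``t`` contains every subject with neither an event nor a
  censoring strictly before ``t``, excluding subjects whose event falls
  exactly at ``t`` (they are no longer under observation at ``t``).
* When the final risk-set step has ``d == n`` (everyone fails), the failure
  estimate is 1 and the Greenwood sum is undefined; the estimate is flagged
  rather than given a fabricated standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@lru_cache(maxsize=32)
def normal_quantile(p: float) -> float:
    """Cached standard-normal quantile (hot path in simulation loops)."""
    return float(stats.norm.ppf(p))


@dataclass(frozen=True)
class SurvivalEstimate:
    """Net failure and its uncertainty at one horizon.

    ``failure`` is F-hat(t) = 1 - KM survival; ``greenwood_se`` is the
    Greenwood standard error of F-hat(t) (identical to that of survival).
    ``ci_low``/``ci_high`` are the complementary log-log reporting interval
    on the failure scale.
    """

    t: float
    failure: float
    greenwood_se: float
    n_at_risk_at_t: int
    n_events_by_t: int
    n_entered: int
    ci_low: float
    ci_high: float
    extrapolated: bool = False  # t lies beyond the last observed time
    se_undefined: bool = False  # terminal d == n step: no Greenwood variance


@dataclass(frozen=True)
class RiskTable:
    """Product-limit bookkeeping: per distinct event time, the risk set
    just before it, the events at it and the censorings before the next."""

    times: np.ndarray      # distinct event times, increasing
    n_at_risk: np.ndarray  # at risk just before each time
    n_events: np.ndarray
    n_censored: np.ndarray  # censorings in [time_i, time_{i+1})


def _as_arrays(times: Sequence[float] | np.ndarray,
               events: Sequence[bool] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d and the same length")
    if t.size == 0:
        raise ValueError("empty event-time collection")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("event times must be positive and finite")
    return t, e


def build_risk_table(times, events) -> RiskTable:
    t, e = _as_arrays(times, events)
    order = np.sort(t)
    tau, d = np.unique(t[e], return_counts=True)
    n_at = t.size - np.searchsorted(order, tau, side="left")
    # censorings in [tau_i, tau_{i+1}); a censoring recorded exactly at an
    # event time belongs to that time's interval (it leaves after the events)
    cens_sorted = np.sort(t[~e])
    lo = np.searchsorted(cens_sorted, tau, side="left")
    hi = np.searchsorted(cens_sorted, np.append(tau[1:], np.inf), side="left")
    return RiskTable(tau, n_at, d, hi - lo)


def n_at_risk(times, events, t: float) -> int:
    """Subjects still under observation at ``t``: no event or censoring
    strictly before ``t`` and no event exactly at ``t``."""
    tt, e = _as_arrays(times, events)
    if t < 0:
        raise ValueError("t must be non-negative")
    return int(np.count_nonzero((tt > t) | ((tt == t) & ~e)))


def km_failure_at(times, events, t_eval: float, *,
                  level: float = 0.95) -> SurvivalEstimate:
    """Net failure F-hat(t) = 1 - prod_{tau_i <= t}(1 - d_i/n_i) with the
    Greenwood variance S-hat(t)^2 * sum d_i / (n_i (n_i - d_i)).

    Evaluating beyond the last observed time returns the last value flagged
    ``extrapolated`` (never silently extended).
    """
    t, e = _as_arrays(times, events)
    if t_eval <= 0:
        raise ValueError("t_eval must be positive")
    order = np.sort(t)
    mask = e & (t <= t_eval)
    tau, d = np.unique(t[mask], return_counts=True)
    n_at = t.size - np.searchsorted(order, tau, side="left")

    exhausted = d >= n_at  # terminal step where everyone at risk fails
    if np.any(exhausted):
        failure, var = 1.0, float("nan")
        se_undefined = True
    else:
        surv = float(np.prod(1.0 - d / n_at))
        gw_sum = float(np.sum(d / (n_at * (n_at - d))))
        failure = 1.0 - surv
        var = surv * surv * gw_sum
        se_undefined = False
    se = float(np.sqrt(var)) if not se_undefined else float("nan")

    at_risk = int(np.count_nonzero((t > t_eval) | ((t == t_eval) & ~e)))
    est = SurvivalEstimate(
        t=float(t_eval),
        failure=failure,
        greenwood_se=se,
        n_at_risk_at_t=at_risk,
        n_events_by_t=int(np.count_nonzero(mask)),
        n_entered=int(t.size),
        ci_low=float("nan"),
        ci_high=float("nan"),
        extrapolated=bool(t_eval > order[-1]),
        se_undefined=se_undefined,
    )
    low, high = loglog_ci(est, level=level)
    return replace(est, ci_low=low, ci_high=high)


def loglog_ci(estimate: SurvivalEstimate, level: float = 0.95) -> tuple[float, float]:
    """Complementary log-log confidence interval for net failure.

    The interval is computed on log(-log S) and mapped back, giving
    [1 - S^exp(-z se*), 1 - S^exp(z se*)] with se* = se / (S |log S|).
    Degenerate estimates are handled by documented rules rather than
    failure: F-hat = 0 returns [0, 1 - (alpha/2)^(1/n)] (the exact
    no-event upper bound on the risk set, the 'rule of three' family);
    F-hat = 1 returns the mirrored [(alpha/2)^(1/n), 1].
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a2 = (1.0 - level) / 2.0
    f = estimate.failure
    n = estimate.n_at_risk_at_t if estimate.n_at_risk_at_t > 0 else estimate.n_entered
    if f <= 0.0:
        return 0.0, 1.0 - a2 ** (1.0 / n)
    if f >= 1.0 or estimate.se_undefined or estimate.greenwood_se == 0.0:
        if f >= 1.0:
            return a2 ** (1.0 / max(estimate.n_entered, 1)), 1.0
        return f, f  # zero-variance interior point: degenerate interval
    s = 1.0 - f
    z = normal_quantile(1.0 - a2)
    se_ll = estimate.greenwood_se / (s * abs(np.log(s)))
    low = 1.0 - s ** np.exp(-z * se_ll)
    high = 1.0 - s ** np.exp(z * se_ll)
    return float(low), float(high)


@dataclass(frozen=True)
class BootstrapSE:
    se: float
    n_used: int
    n_dropped: int
    warn: bool  # > 10% of resamples were degenerate at t


def bootstrap_se_oracle(times, events, t_eval: float, n_boot: int,
                        seed: int) -> BootstrapSE:
    """Nonparametric bootstrap standard error of F-hat(t): resample
    subjects with replacement and recompute the product-limit estimate.

    Serves as an independent check on the Greenwood formula.  Resamples
    with zero subjects at risk at ``t_eval`` are dropped and counted; if
    more than 10% are dropped the result carries a warning flag.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    t, e = _as_arrays(times, events)
    rng = np.random.default_rng(seed)
    n = t.size
    vals = []
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        bt, be = t[idx], e[idx]
        if not np.any((bt > t_eval) | ((bt == t_eval) & ~be)):
            dropped += 1
            continue
        vals.append(km_failure_at(bt, be, t_eval).failure)
    arr = np.asarray(vals)
    return BootstrapSE(
        se=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        n_used=int(arr.size),
        n_dropped=dropped,
        warn=dropped > 0.1 * n_boot,
    )


def read_event_times_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Convenience reader for a two-column ``time_years,event`` CSV."""
    df = pd.read_csv(path)
    return df["time_years"].to_numpy(float), df["event"].to_numpy(bool)
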