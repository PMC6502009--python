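"""Reference selection, failure-difference testing and trichotomous
classification of prosthesis constructs.

Within each stratum and at each horizon the benchmark (reference) is the
construct with the lowest estimated net failure among constructs with at
least ``min_reference`` (default 1000) procedures still at risk.  Every
sufficiently used construct is then compared with the reference on the
failure-difference scale:

    diff    = F_x(t) - F_ref(t)
    SE(diff) = sqrt(GSE_x^2 + GSE_ref^2)          (pooled Greenwood SE)
    z(m)    = (diff - delta_m) / SE(diff)

where the non-inferiority margin ``delta_m = m * F_ref(t)`` states an
``m``-fold relative increase in failure risk (m = 0.2 and m = 1.0 by
default) as an absolute failure-probability excess at the horizon.  z is
oriented so that large negative values support non-inferiority.

Classification follows the difference's two-sided Wald confidence interval:

* ``non_inferior``  — upper limit <= delta_20 (inclusive);
* ``inferior_100``  — lower limit > delta_100;
* ``inferior_20``   — lower limit > delta_20 (and not inferior_100);
* ``inconclusive``  — otherwise (the interval straddles the margin).

The labels are exhaustive and mutually exclusive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from .km_survival import SurvivalEstimate, km_failure_at, normal_quantile
from .registry_io import ConstructKey, Stratum


class Classification(str, enum.Enum):
    NON_INFERIOR = "non_inferior"
    INCONCLUSIVE = "inconclusive"
    INFERIOR_20 = "inferior_20"
    INFERIOR_100 = "inferior_100"


@dataclass(frozen=True)
class MarginSpec:
    """A non-inferiority margin: relative risk increase ``m`` absolutised
    against the reference failure, ``delta = m * F_ref(t)``."""

    relative_margin: float
    delta: float


def noninferiority_margin(f_ref: float, m: float) -> MarginSpec:
    if not 0.0 <= f_ref <= 1.0:
        raise ValueError("reference failure must be a probability")
    if m <= 0:
        raise ValueError("relative margin must be positive")
    return MarginSpec(relative_margin=m, delta=m * f_ref)


@dataclass(frozen=True)
class ReferenceSelection:
    """Outcome of reference selection for one stratum x horizon."""

    construct: Optional[ConstructKey]
    estimate: Optional[SurvivalEstimate]
    eligible_pool: list[tuple[ConstructKey, SurvivalEstimate]]
    mode: str = "contemporary"  # or "historic"

    @property
    def found(self) -> bool:
        return self.construct is not None


def select_reference(candidates: Sequence[tuple[ConstructKey, SurvivalEstimate]],
                     min_at_risk: int = 1000,
                     mode: str = "contemporary") -> ReferenceSelection:
    """Pick the lowest-failure construct among those with at least
    ``min_at_risk`` procedures still at risk at the horizon.

    Ties break toward the larger risk set, then the lexicographically
    smaller construct key.  An empty eligible pool yields an explicit
    "no reference" selection rather than an exception.
    """
    pool = [(k, e) for k, e in candidates if e.n_at_risk_at_t >= min_at_risk]
    if not pool:
        return ReferenceSelection(None, None, [], mode=mode)
    best = min(pool, key=lambda ke: (ke[1].failure, -ke[1].n_at_risk_at_t, ke[0]))
    return ReferenceSelection(best[0], best[1], pool, mode=mode)


@dataclass(frozen=True)
class DifferenceTest:
    """The failure difference against one margin (no classification yet)."""

    t: float
    diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    delta: float
    z: float
    degenerate: bool = False  # pooled SE was zero: point interval


def failure_difference_test(est_x: SurvivalEstimate,
                            est_ref: SurvivalEstimate,
                            margin: MarginSpec,
                            alpha: float = 0.05) -> DifferenceTest:
    """z-test of the net-failure difference against an absolute margin.

    ``diff`` carries a Wald interval ``diff +/- z_{1-alpha/2} SE(diff)``
    with the pooled Greenwood SE; ``z = (diff - delta)/SE(diff)`` so that
    z below the critical value supports non-inferiority.  A zero pooled SE
    (no events in either arm by ``t``) yields a degenerate point interval
    with an infinite or undefined z, flagged rather than raised.
    """
    if est_x.t != est_ref.t:
        raise ValueError(f"horizon mismatch: {est_x.t} vs {est_ref.t}")
    if math.isnan(est_x.greenwood_se) or math.isnan(est_ref.greenwood_se):
        raise ValueError("Greenwood SE undefined; test cannot be constructed")
    se = math.hypot(est_x.greenwood_se, est_ref.greenwood_se)
    diff = est_x.failure - est_ref.failure
    if se == 0.0:
        shifted = diff - margin.delta
        z = math.copysign(math.inf, shifted) if shifted != 0 else 0.0
        return DifferenceTest(t=est_x.t, diff=diff, se_diff=0.0,
                              ci_low=diff, ci_high=diff, delta=margin.delta,
                              z=z, degenerate=True)
    zc = normal_quantile(1.0 - alpha / 2.0)
    return DifferenceTest(
        t=est_x.t,
        diff=diff,
        se_diff=se,
        ci_low=diff - zc * se,
        ci_high=diff + zc * se,
        delta=margin.delta,
        z=(diff - margin.delta) / se,
    )


def classify_construct(ci_low: float, ci_high: float,
                       delta20: MarginSpec, delta100: MarginSpec) -> Classification:
    """Apply the trichotomous classification rules to a difference CI.

    The non-inferiority comparison is inclusive (``<=``); the inferiority
    comparisons are strict (``>``), so a lower limit exactly on the margin
    is not inferior.
    """
    if delta20.delta > delta100.delta:
        raise ValueError("delta20 must not exceed delta100")
    if ci_high <= delta20.delta:
        return Classification.NON_INFERIOR
    if ci_low > delta100.delta:
        return Classification.INFERIOR_100
    if ci_low > delta20.delta:
        return Classification.INFERIOR_20
    return Classification.INCONCLUSIVE


@dataclass(frozen=True)
class NonInferiorityResult:
    """One construct's comparison against the stratum reference."""

    construct: ConstructKey
    t: float
    f_x: float
    f_ref: float
    diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    z_20: float
    z_100: float
    delta_20: float
    delta_100: float
    classification: Classification
    n_at_risk: int
    se_x: float
    is_reference: bool = False
    display_eligible: bool = False
    ref_construct: Optional[ConstructKey] = None
    stratum: Optional[Stratum] = None


def compare_to_reference(construct: ConstructKey,
                         est_x: SurvivalEstimate,
                         ref: ReferenceSelection,
                         margins: tuple[float, float] = (0.2, 1.0),
                         alpha: float = 0.05,
                         min_display: int = 500) -> NonInferiorityResult:
    """Full comparison of one construct with the selected reference,
    including both margins and the classification label."""
    assert ref.construct is not None and ref.estimate is not None
    m20 = noninferiority_margin(ref.estimate.failure, margins[0])
    m100 = noninferiority_margin(ref.estimate.failure, margins[1])
    t20 = failure_difference_test(est_x, ref.estimate, m20, alpha=alpha)
    t100 = failure_difference_test(est_x, ref.estimate, m100, alpha=alpha)
    label = classify_construct(t20.ci_low, t20.ci_high, m20, m100)
    return NonInferiorityResult(
        construct=construct,
        t=est_x.t,
        f_x=est_x.failure,
        f_ref=ref.estimate.failure,
        diff=t20.diff,
        se_diff=t20.se_diff,
        ci_low=t20.ci_low,
        ci_high=t20.ci_high,
        z_20=t20.z,
        z_100=t100.z,
        delta_20=m20.delta,
        delta_100=m100.delta,
        classification=label,
        n_at_risk=est_x.n_at_risk_at_t,
        se_x=est_x.greenwood_se,
        is_reference=construct == ref.construct,
        display_eligible=est_x.n_at_risk_at_t >= min_display,
        ref_construct=ref.construct,
    )


@dataclass
class StratumBenchmark:
    """Results of benchmarking one stratum at one horizon."""

    results: list[NonInferiorityResult]
    reference: ReferenceSelection
    status: str  # "ok" or "no_reference"
    estimates: dict[ConstructKey, SurvivalEstimate] = field(default_factory=dict)


def benchmark_stratum(groups: Mapping[ConstructKey, tuple[np.ndarray, np.ndarray]],
                      t: float,
                      *,
                      min_reference: int = 1000,
                      min_display: int = 500,
                      min_tabular: int = 250,
                      margins: tuple[float, float] = (0.2, 1.0),
                      alpha: float = 0.05,
                      forced_reference: Optional[ConstructKey] = None,
                      estimates: Optional[Mapping[ConstructKey, SurvivalEstimate]] = None,
                      ) -> StratumBenchmark:
    """Benchmark every sufficiently used construct in one stratum at ``t``.

    ``groups`` maps each construct to its (times, events) arrays within the
    stratum.  Estimates are computed per construct (or taken from
    ``estimates`` if the caller precomputed them); the reference is chosen
    by :func:`select_reference` unless ``forced_reference`` pins it (the
    historic-reference sensitivity mode).  One result is emitted per
    construct with at least ``min_tabular`` at risk, flagged
    display-eligible at ``min_display``; the reference's own row is kept
    with a zero difference.  Results are ordered by ascending difference
    (ties by construct key, for determinism).
    """
    ests: dict[ConstructKey, SurvivalEstimate] = dict(estimates) if estimates else {
        key: km_failure_at(times, events, t)
        for key, (times, events) in groups.items()
    }
    candidates = sorted(ests.items())
    if forced_reference is not None:
        if forced_reference not in ests:
            return StratumBenchmark([], ReferenceSelection(None, None, [],
                                                           mode="historic"),
                                    "no_reference", ests)
        ref = ReferenceSelection(forced_reference, ests[forced_reference],
                                 [(forced_reference, ests[forced_reference])],
                                 mode="historic")
    else:
        ref = select_reference(candidates, min_at_risk=min_reference)
    if not ref.found:
        return StratumBenchmark([], ref, "no_reference", ests)

    results = [
        compare_to_reference(key, est, ref, margins=margins, alpha=alpha,
                             min_display=min_display)
        for key, est in candidates
        if (est.n_at_risk_at_t >= min_tabular or key == ref.construct)
        and not est.se_undefined
    ]
    results.sort(key=lambda r: (r.diff, r.construct))
    return StratumBenchmark(results, ref, "ok", ests)
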