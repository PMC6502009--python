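import datetime as dt

import numpy as np
import pytest

from implantbench.km_survival import SurvivalEstimate


@pytest.fixture
def worked_example():
    """Five subjects: event at 1, censor at 2, event at 4, censor at 6 and 7.

    Hand product-limit at t=5: F = 1 - (4/5)(2/3) = 7/15;
    Greenwood var = (8/15)^2 (1/(5*4) + 1/(3*2)).
    """
    times = np.array([1.0, 2.0, 4.0, 6.0, 7.0])
    events = np.array([True, False, True, False, False])
    return times, events


@pytest.fixture
def registry_csv(tmp_path):
    """Write a small registry CSV and return its path."""

    def _write(rows, header="procedure_id,gender,age,stem,cup,bearing,"
                           "primary_date,revision_date,death_date,traceable"):
        path = tmp_path / "registry.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return _write


def make_estimate(failure, se, t=5.0, n_at_risk=1000, n_entered=2000):
    """Build a SurvivalEstimate directly for margin/classification tests."""
    return SurvivalEstimate(
        t=t, failure=failure, greenwood_se=se, n_at_risk_at_t=n_at_risk,
        n_events_by_t=int(round(failure * n_entered)), n_entered=n_entered,
        ci_low=max(failure - 1.96 * se, 0.0), ci_high=failure + 1.96 * se)


def censored_sample(rng, n, *, event_rate=0.12, t_max=10.0):
    """An exponential-failure, uniformly censored sample for SE checks."""
    fail = rng.exponential(1.0 / event_rate, n)
    cens = rng.uniform(0.5, t_max, n)
    times = np.minimum(fail, cens)
    events = fail <= cens
    return times, events
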