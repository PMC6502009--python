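import numpy as np
import pytest

from conftest import make_estimate
from implantbench.km_survival import km_failure_at
from implantbench.noninferiority import (Classification, benchmark_stratum,
                                         classify_construct,
                                         compare_to_reference,
                                         failure_difference_test,
                                         noninferiority_margin,
                                         select_reference)
from implantbench.registry_io import ConstructKey


def key(name):
    return ConstructKey.of(name, "cup", "MoP")


class TestMargin:
    def test_twenty_percent_of_reference(self):
        m = noninferiority_margin(0.0214, 0.2)
        assert m.delta == pytest.approx(0.00428)

    def test_zero_reference_gives_zero_margin(self):
        assert noninferiority_margin(0.0, 0.2).delta == 0.0

    def test_doubling_margin(self):
        assert noninferiority_margin(0.0055, 1.0).delta == pytest.approx(0.0055)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            noninferiority_margin(1.5, 0.2)
        with pytest.raises(ValueError):
            noninferiority_margin(0.02, 0.0)


class TestSelectReference:
    def test_lowest_failure_wins(self):
        cands = [(key("a"), make_estimate(0.0120, 0.002, n_at_risk=1200)),
                 (key("b"), make_estimate(0.0039, 0.0015, n_at_risk=1554)),
                 (key("c"), make_estimate(0.0080, 0.002, n_at_risk=3000))]
        ref = select_reference(cands)
        assert ref.construct == key("b")
        assert ref.estimate.failure == pytest.approx(0.0039)

    def test_threshold_filters_pool(self):
        cands = [(key("small"), make_estimate(0.001, 0.001, n_at_risk=999)),
                 (key("big"), make_estimate(0.02, 0.003, n_at_risk=1000))]
        ref = select_reference(cands)
        assert ref.construct == key("big")
        assert len(ref.eligible_pool) == 1

    def test_singleton_pool_selected_regardless_of_failure(self):
        ref = select_reference([(key("only"), make_estimate(0.4, 0.01,
                                                            n_at_risk=1500))])
        assert ref.construct == key("only")

    def test_tie_breaks_by_larger_risk_set_then_key(self):
        a = (key("a"), make_estimate(0.01, 0.002, n_at_risk=1200))
        b = (key("b"), make_estimate(0.01, 0.002, n_at_risk=1500))
        assert select_reference([a, b]).construct == key("b")
        c = (key("c"), make_estimate(0.01, 0.002, n_at_risk=1500))
        assert select_reference([b, c]).construct == key("b")

    def test_empty_pool_is_a_status_not_an_exception(self):
        ref = select_reference([])
        assert not ref.found
        ref = select_reference([(key("a"), make_estimate(0.01, 0.002,
                                                         n_at_risk=10))])
        assert not ref.found


class TestDifferenceTest:
    def test_worked_arithmetic(self):
        est_x = make_estimate(0.05, 0.01)
        est_ref = make_estimate(0.02, 0.005)
        m = noninferiority_margin(0.02, 0.2)
        res = failure_difference_test(est_x, est_ref, m)
        assert res.diff == pytest.approx(0.03)
        assert res.se_diff == pytest.approx(np.sqrt(1.25) / 100)  # 1.118%
        assert res.ci_low == pytest.approx(0.00808, abs=5e-5)
        assert res.ci_high == pytest.approx(0.05192, abs=5e-5)
        assert res.z == pytest.approx((0.03 - 0.004) / 0.011180, abs=1e-3)

    def test_self_comparison_is_centred_on_zero(self):
        est = make_estimate(0.02, 0.005)
        res = failure_difference_test(est, est, noninferiority_margin(0.02, 0.2))
        assert res.diff == 0.0
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_horizon_mismatch_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="horizon"):
            failure_difference_test(make_estimate(0.05, 0.01, t=3.0),
                                    make_estimate(0.02, 0.005, t=5.0),
                                    noninferiority_margin(0.02, 0.2))

    def test_zero_pooled_se_degenerates_to_point_interval(self):
        est = make_estimate(0.0, 0.0)
        res = failure_difference_test(est, est, noninferiority_margin(0.0, 0.2))
        assert res.degenerate
        assert res.ci_low == res.ci_high == 0.0


class TestClassification:
    d20 = noninferiority_margin(0.02, 0.2)   # delta = 0.004
    d100 = noninferiority_margin(0.02, 1.0)  # delta = 0.020

    def classify(self, lo, hi):
        return classify_construct(lo, hi, self.d20, self.d100)

    def test_ci_wholly_below_margin_is_non_inferior(self):
        assert self.classify(-0.010, -0.005) is Classification.NON_INFERIOR

    def test_rule_application_to_worked_example(self):
        assert self.classify(0.00808, 0.05192) is Classification.INFERIOR_20

    def test_upper_limit_exactly_on_margin_is_non_inferior(self):
        assert self.classify(0.001, 0.004) is Classification.NON_INFERIOR

    def test_lower_limit_exactly_on_margin_is_not_inferior(self):
        assert self.classify(0.004, 0.03) is Classification.INCONCLUSIVE

    def test_lower_limit_above_large_margin_is_inferior_100(self):
        assert self.classify(0.021, 0.04) is Classification.INFERIOR_100

    def test_straddling_interval_is_inconclusive(self):
        assert self.classify(-0.001, 0.03) is Classification.INCONCLUSIVE

    def test_inferior_100_implies_inferior_20_condition(self):
        lo = 0.021
        assert lo > self.d100.delta and lo > self.d20.delta

    def test_misordered_margins_rejected(self):
        with pytest.raises(ValueError):
            classify_construct(0.0, 0.01, self.d100, self.d20)


def _exponential_groups(rng, spec, t_censor=12.0):
    """spec: list of (name, true_failure_at_5y, n) with exponential times."""
    groups = {}
    for name, f5, n in spec:
        rate = -np.log1p(-f5) / 5.0
        fail = rng.exponential(1.0 / rate, n)
        cens = rng.uniform(6.0, t_censor, n)
        times = np.minimum(fail, cens)
        events = fail <= cens
        groups[key(name)] = (times, events)
    return groups


class TestBenchmarkStratum:
    def test_empty_eligibility_reports_status(self):
        rng = np.random.default_rng(0)
        groups = _exponential_groups(rng, [("a", 0.02, 100), ("b", 0.03, 150)])
        bench = benchmark_stratum(groups, 5.0)
        assert bench.status == "no_reference" and bench.results == []

    def test_reference_row_has_zero_diff_and_flag(self):
        rng = np.random.default_rng(1)
        groups = _exponential_groups(rng, [("a", 0.02, 2000), ("b", 0.05, 2000)])
        bench = benchmark_stratum(groups, 5.0)
        assert bench.status == "ok"
        ref_rows = [r for r in bench.results if r.is_reference]
        assert len(ref_rows) == 1
        assert ref_rows[0].diff == 0.0
        assert ref_rows[0].construct == bench.reference.construct

    def test_results_sorted_ascending_by_diff(self):
        rng = np.random.default_rng(2)
        groups = _exponential_groups(
            rng, [("a", 0.02, 2000), ("b", 0.06, 2000), ("c", 0.04, 2000)])
        bench = benchmark_stratum(groups, 5.0)
        diffs = [r.diff for r in bench.results]
        assert diffs == sorted(diffs)

    def test_tabular_and_display_thresholds(self):
        rng = np.random.default_rng(3)
        groups = _exponential_groups(
            rng, [("ref", 0.02, 3000), ("mid", 0.03, 400), ("tiny", 0.03, 100)])
        bench = benchmark_stratum(groups, 5.0)
        names = {r.construct.stem for r in bench.results}
        assert "tiny" not in names and {"ref", "mid"} <= names
        mid = next(r for r in bench.results if r.construct.stem == "mid")
        assert not mid.display_eligible  # ~390 at risk at 5y: tabular only
        ref = next(r for r in bench.results if r.is_reference)
        assert ref.display_eligible

    def test_forced_reference_mode(self):
        rng = np.random.default_rng(4)
        groups = _exponential_groups(rng, [("a", 0.02, 2000), ("b", 0.05, 2000)])
        bench = benchmark_stratum(groups, 5.0, forced_reference=key("b"))
        assert bench.reference.construct == key("b")
        assert bench.reference.mode == "historic"
        missing = benchmark_stratum(groups, 5.0, forced_reference=key("zz"))
        assert missing.status == "no_reference"

    def test_known_truth_flags_only_the_bad_construct(self):
        # 2% / 2% / 6% true failure at 5 years, n=2000 each: the 6% one is
        # inferior, the other 2% one is not (one of them is the reference)
        rng = np.random.default_rng(5)
        groups = _exponential_groups(
            rng, [("a", 0.02, 2000), ("b", 0.02, 2000), ("bad", 0.06, 2000)])
        bench = benchmark_stratum(groups, 5.0)
        by = {r.construct.stem: r.classification for r in bench.results}
        assert by["bad"] in (Classification.INFERIOR_20,
                             Classification.INFERIOR_100)
        assert by["a"] not in (Classification.INFERIOR_20,
                               Classification.INFERIOR_100)
        assert by["b"] not in (Classification.INFERIOR_20,
                               Classification.INFERIOR_100)
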