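import math

import numpy as np
import pytest

from wgdkit.patterns import pattern_suite
from wgdkit.retention import (
    RetentionError,
    conditional_retention,
    expected_copies,
    lineage_table,
    opportunities,
    pooled_two_proportion_z,
    retention_report,
)
from wgdkit.simulate import SimParams, sim_families


class TestExpectedCopies:
    @pytest.mark.parametrize("n,base,expected", [(0, 1, 1), (1, 1, 2), (2, 1, 4), (2, 3, 12)])
    def test_doubling(self, n, base, expected):
        assert expected_copies(n, base) == expected

    def test_negative_rejected(self):
        with pytest.raises(RetentionError):
            expected_copies(-1)


def _table_for(rigid, *names):
    fams = [rigid.classify_family(pattern_suite()[n]) for n in names]
    return lineage_table(fams, rigid)


class TestOpportunities:
    def test_full_retention_pattern(self, rigid):
        table = _table_for(rigid, "f")
        assert (opportunities(table, "4R").retained, opportunities(table, "4R").total) == (2, 2)
        assert (opportunities(table, "3R").retained, opportunities(table, "3R").total) == (1, 1)

    def test_3r_without_4r(self, rigid):
        table = _table_for(rigid, "g")
        assert (opportunities(table, "4R").retained, opportunities(table, "4R").total) == (0, 2)

    def test_4r_only(self, rigid):
        table = _table_for(rigid, "n")
        assert (opportunities(table, "3R").retained, opportunities(table, "3R").total) == (0, 1)
        assert (opportunities(table, "4R").retained, opportunities(table, "4R").total) == (1, 1)

    def test_tandems_on_every_retained_4r_lineage(self, rigid):
        table = _table_for(rigid, "e")
        est = conditional_retention(table, "post4R", {"4R": True})
        assert (est.retained, est.total) == (4, 4)

    def test_condition_always_true_equals_marginal(self, rigid):
        table = _table_for(rigid, "a", "f", "g", "n", "o", "p")
        marginal = opportunities(table, "4R")
        t = conditional_retention(table, "4R", {"3R": True})
        f = conditional_retention(table, "4R", {"3R": False})
        assert t.retained + f.retained == marginal.retained
        assert t.total + f.total == marginal.total

    def test_zero_opportunities_flagged_not_zero(self, rigid):
        table = _table_for(rigid, "p")
        est = opportunities(table, "4R", given={"3R": True})
        assert est.undefined and est.probability is None


class TestConditionalSimulated:
    def test_ssd_retention_conditional_on_wgd(self, rigid):
        params = SimParams(q3=0.55, q4=0.5, ssd_rate=0.0,
                           post4R_prob_given_4R=0.8, post4R_prob_no_4R=0.4, seed=42)
        fams = [rigid.classify_family(t) for t, _ in sim_families(2000, params)]
        table = lineage_table(fams, rigid)
        for flag, p_true in ((True, 0.8), (False, 0.4)):
            est = conditional_retention(table, "post4R", {"4R": flag})
            sd = math.sqrt(p_true * (1 - p_true) / est.total)
            assert abs(est.probability - p_true) < 3 * sd

    def test_joint_counts_bounded_by_marginals(self, rigid):
        params = SimParams(seed=9, ssd_rate=0.5)
        fams = [rigid.classify_family(t) for t, _ in sim_families(300, params)]
        table = lineage_table(fams, rigid)
        for cls in ("4R", "post3R_pre4R", "post4R"):
            marg = opportunities(table, cls)
            cond = conditional_retention(table, cls, {"3R": True})
            assert cond.retained <= marg.retained
            assert cond.total <= marg.total
            if not marg.undefined:
                assert 0.0 <= marg.probability <= 1.0


class TestPooledZTest:
    def test_equal_proportions(self):
        zt = pooled_two_proportion_z(50, 100, 50, 100)
        assert zt.z == 0.0 and zt.p_value == pytest.approx(1.0)

    def test_known_value(self):
        zt = pooled_two_proportion_z(60, 100, 40, 100)
        assert zt.z == pytest.approx(2.8284, abs=1e-4)
        assert zt.p_value == pytest.approx(0.00468, abs=1e-5)

    def test_antisymmetry(self):
        a = pooled_two_proportion_z(60, 100, 40, 100)
        b = pooled_two_proportion_z(40, 100, 60, 100)
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_pooled_proportion_flagged(self):
        assert pooled_two_proportion_z(0, 10, 0, 20).undefined
        assert pooled_two_proportion_z(10, 10, 20, 20).undefined

    def test_invalid_counts(self):
        with pytest.raises(RetentionError):
            pooled_two_proportion_z(5, 4, 1, 10)

    def test_against_reference_implementation(self):
        from statsmodels.stats.proportion import proportions_ztest
        rng = np.random.default_rng(123)
        for _ in range(300):
            n1, n2 = rng.integers(2, 400, size=2)
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            zt = pooled_two_proportion_z(x1, int(n1), x2, int(n2))
            if zt.undefined:
                continue
            z_ref, p_ref = proportions_ztest([x1, x2], [n1, n2])
            assert abs(zt.z - z_ref) < 1e-10
            assert abs(zt.p_value - p_ref) < 1e-10


class TestReport:
    def test_report_structure(self, rigid):
        fams = [rigid.classify_family(t) for t, _ in
                sim_families(100, SimParams(seed=3, ssd_rate=0.4))]
        report = retention_report(lineage_table(fams, rigid), rigid)
        assert set(report["classes"]) == {"3R", "4R", "post3R_pre4R", "post4R"}
        for entry in report["classes"].values():
            assert entry["retained"] <= entry["opportunities"]
        assert "4R|3R" in report["conditionals"]
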