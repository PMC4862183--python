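import collections

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wgdkit.expression import (
    CONSERVED,
    FLAT_CLUSTER,
    NEOFUNCTIONALIZED,
    SUBFUNCTIONALIZED,
    UNCLASSIFIED,
    ExpressionError,
    ExpressionTriplet,
    classify_cohort,
    classify_triplet,
    coexpression_clusters,
    onoff,
    onoff_divergence,
    pearson_test,
    summarize_divergence,
)
from wgdkit.simulate import ExprSimParams, sim_triplets


class TestPearson:
    def test_identity(self):
        x = np.array([1.0, 2, 3, 4, 5, 9])
        r, p = pearson_test(x, x)
        assert r == pytest.approx(1.0) and p < 1e-6

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(1)
        for n in (6, 10, 15):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p = pearson_test(x, y)
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            assert p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), rel=1e-9)

    def test_critical_r_at_n6(self):
        # the borderline case: r = 0.75 with six samples is not two-sided
        # significant at 0.05 (p ~ 0.086) but is one-sided (p ~ 0.043)
        x = np.arange(6.0)
        y = 0.75 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.75 ** 2) * _orth(x)
        r, p_two = pearson_test(x, y)
        assert r == pytest.approx(0.75, abs=1e-9)
        assert p_two == pytest.approx(0.0859, abs=1e-3)
        _, p_one = pearson_test(x, y, alternative="greater")
        assert p_one == pytest.approx(p_two / 2, rel=1e-9)

    def test_zero_correlation(self):
        x = np.arange(6.0)
        r, p = pearson_test(x, _orth(x))
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_profile_flagged(self):
        with pytest.raises(ExpressionError):
            pearson_test([1, 1, 1, 1], [1, 2, 3, 4])


def _orth(x):
    """A unit-variance vector exactly orthogonal to x (after centering)."""
    rng = np.random.default_rng(7)
    y = rng.normal(size=len(x))
    xc = x - x.mean()
    y = y - y.mean()
    y = y - (y @ xc) / (xc @ xc) * xc
    return (y - y.mean()) / y.std()


class TestOnOff:
    @pytest.mark.parametrize("profile,tau,expected", [
        ([0, 0, 0], 1.0, [False, False, False]),
        ([0.5, 2, 0], 1.0, [False, True, False]),
        ([0.1, 3, 0.2], 0.0, [True, True, True]),
    ])
    def test_thresholding(self, profile, tau, expected):
        assert list(onoff(profile, tau)) == expected

    def test_negative_tau_rejected(self):
        with pytest.raises(ExpressionError):
            onoff([1.0, 2.0], -1)

    def test_onoff_divergence_partition(self):
        og = np.array([5, 5, 5, 5, 0.0, 0])
        t = ExpressionTriplet(np.array([5, 5, 0, 0, 0.0, 0]),
                              np.array([0, 0, 5, 5, 0.0, 0]), og)
        assert onoff_divergence(t) == SUBFUNCTIONALIZED
        t2 = ExpressionTriplet(og.copy(), np.array([0, 0, 0, 0, 5, 0.0]), og)
        assert onoff_divergence(t2) == NEOFUNCTIONALIZED


class TestClustering:
    def _two_groups(self):
        rng = np.random.default_rng(0)
        a = np.array([9, 9, 9, 1, 1, 1, 1, 1.0])
        b = np.array([1, 1, 1, 9, 9, 9, 1, 1.0])
        rows = {}
        for i in range(6):
            base = a if i < 3 else b
            rows[f"g{i}"] = base * np.exp(rng.normal(0, 0.05, len(base)))
        return pd.DataFrame(rows).T

    def test_template_groups_recovered(self):
        m = self._two_groups()
        labels = coexpression_clusters(m, k=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_k_equals_n_gives_singletons(self):
        m = self._two_groups()
        labels = coexpression_clusters(m, k=len(m))
        assert labels.nunique() == len(m)

    def test_identical_profiles_cocluster(self):
        m = self._two_groups()
        m.loc["g0"] = m.loc["g1"]
        for k in (2, 3, 4):
            labels = coexpression_clusters(m, k=k)
            assert labels["g0"] == labels["g1"]

    def test_constant_profile_goes_to_flat_cluster(self):
        m = self._two_groups()
        m.loc["flat"] = 3.0
        labels = coexpression_clusters(m, k=2)
        assert labels["flat"] == FLAT_CLUSTER

    def test_determinism(self):
        m = self._two_groups()
        l1 = coexpression_clusters(m)
        l2 = coexpression_clusters(m.copy())
        assert (l1 == l2).all()


class TestClassifyTriplet:
    def _call(self, d1, d2, og, labels=("c1", "c2")):
        t = ExpressionTriplet(np.asarray(d1, float), np.asarray(d2, float),
                              np.asarray(og, float), name="t")
        return classify_triplet(t, {"t.1": labels[0], "t.2": labels[1]})

    def test_identical_duplicates_conserved(self):
        og = [8, 1, 1, 8, 1, 1, 8, 1, 1, 8, 1, 1]
        call = self._call(og, og, og, labels=("c1", "c1"))
        assert call.call == CONSERVED

    def test_one_conserved_copy_is_neofunctionalization(self):
        rng = np.random.default_rng(3)
        og = np.exp(rng.normal(0, 1, 15)) + 0.1
        d1 = og * np.exp(rng.normal(0, 0.05, 15))
        d2 = np.exp(rng.normal(0, 1, 15)) + 0.1
        call = self._call(d1, d2, og)
        assert call.call == NEOFUNCTIONALIZED

    def test_complementary_halves_are_subfunctionalization(self):
        rng = np.random.default_rng(4)
        og = np.exp(rng.normal(np.log(8), 0.1, 15))
        og[0] = 0.4
        d1, d2 = np.zeros(15), np.zeros(15)
        d1[1:8] = np.exp(rng.normal(np.log(8), 0.1, 7))
        d2[8:] = np.exp(rng.normal(np.log(8), 0.1, 7))
        call = self._call(d1, d2, og)
        assert call.call == SUBFUNCTIONALIZED
        assert call.p_sum < 0.03 < call.p_dup1 and call.p_dup2 > 0.05

    def test_buffer_zone_unclassified(self):
        # duplicates whose correlations fall between the on/off thresholds
        # must not be called either way
        rng = np.random.default_rng(11)
        for _ in range(200):
            og = np.exp(rng.normal(0, 1, 15))
            d1 = og * np.exp(rng.normal(0, 1.2, 15))
            d2 = og * np.exp(rng.normal(0, 1.2, 15))
            call = self._call(d1, d2, og)
            if 0.03 <= call.p_dup1 <= 0.05 and 0.03 <= call.p_dup2 <= 0.05:
                assert call.call == UNCLASSIFIED

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        og = np.exp(rng.normal(0, 1, 15))
        d1 = og * np.exp(rng.normal(0, 0.1, 15))
        d2 = np.exp(rng.normal(0, 1, 15))
        a = self._call(d1, d2, og)
        b = self._call(10 * d1, 10 * d2, 10 * og)
        assert a.call == b.call
        assert a.r_dup1 == pytest.approx(b.r_dup1)

    def test_relaxed_sub_variant(self):
        rng = np.random.default_rng(6)
        og = np.exp(rng.normal(np.log(8), 0.1, 15))
        og[0] = 0.4
        d1, d2 = np.zeros(15), np.zeros(15)
        d1[1:13] = og[1:13]          # dominant half: correlates with og
        d2[13:] = np.exp(rng.normal(np.log(8), 0.1, 2))
        t = ExpressionTriplet(d1, d2, og, name="t")
        labels = {"t.1": 1, "t.2": 2}
        strict = classify_triplet(t, labels)
        relaxed = classify_triplet(t, labels, relaxed_sub=True)
        if strict.call != SUBFUNCTIONALIZED and relaxed.p_sum < 0.03:
            assert relaxed.call in (SUBFUNCTIONALIZED, NEOFUNCTIONALIZED)


class TestSummaries:
    def test_empty_input(self):
        s = summarize_divergence([])
        assert s["total"] == 0 and s["diverged_fraction"] == 0.0

    def test_all_conserved(self):
        _, _, _, _ = sim_triplets(ExprSimParams(class_mix=(1.0, 0.0, 0.0),
                                                noise_sd=0.0, seed=0), 30)
        dup, og, table, truth = sim_triplets(
            ExprSimParams(class_mix=(1.0, 0.0, 0.0), noise_sd=0.0, seed=0), 30)
        calls = classify_cohort(dup, og, table)
        s = summarize_divergence(calls)
        assert s["counts"][CONSERVED] == 30
        assert s["diverged_fraction"] == 0.0

    def test_mixture_recovery_single_seed(self):
        dup, og, table, truth = sim_triplets(ExprSimParams(seed=1), 300)
        calls = classify_cohort(dup, og, table)
        conf = collections.Counter((t, c.call) for t, c in zip(truth, calls))
        for cls in (CONSERVED, NEOFUNCTIONALIZED, SUBFUNCTIONALIZED):
            total = sum(v for (t, _), v in conf.items() if t == cls)
            assert conf[(cls, cls)] / total >= 0.9
        s = summarize_divergence(calls)
        assert s["counts"][NEOFUNCTIONALIZED] > s["counts"][SUBFUNCTIONALIZED]
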