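import math

import numpy as np
import pytest

from wgdkit.patterns import PATTERN_EVENT_COUNTS
from wgdkit.retention import expected_copies
from wgdkit.simulate import (
    ExprSimParams,
    SimParams,
    SimulationError,
    sim_families,
    sim_interactions,
    sim_triplets,
)
from wgdkit.trees import write_newick


class TestFamilySimulator:
    def test_bitwise_reproducibility(self):
        a = sim_families(20, SimParams(seed=99, ssd_rate=0.5, topo_noise=0.2))
        b = sim_families(20, SimParams(seed=99, ssd_rate=0.5, topo_noise=0.2))
        assert [write_newick(t) for t, _ in a] == [write_newick(t) for t, _ in b]

    def test_full_retention_reproduces_doubly_duplicated_pattern(self, rigid):
        params = SimParams(q3=1.0, q4=1.0, ssd_rate=0.0, seed=1)
        for tree, truth in sim_families(10, params):
            fam = rigid.classify_family(tree)
            assert fam.counts() == PATTERN_EVENT_COUNTS["f"]
            n_salmon = sum(1 for l in tree.leaves() if l.species == "salmon")
            assert n_salmon == expected_copies(2, 1)

    def test_no_retention_matches_species_tree(self, rigid):
        params = SimParams(q3=0.0, q4=0.0, ssd_rate=0.0, seed=2)
        for tree, truth in sim_families(10, params):
            fam = rigid.classify_family(tree)
            assert fam.counts() == {}
            assert len(tree) == 7

    def test_retention_frequency_matches_parameter(self):
        params = SimParams(q3=0.5, q4=0.5, ssd_rate=0.0, seed=3)
        sims = sim_families(2000, params)
        freq = sum(tr.three_r for _, tr in sims) / len(sims)
        sd = math.sqrt(0.25 / len(sims))
        assert abs(freq - 0.5) < 3 * sd

    def test_invalid_params_rejected(self):
        with pytest.raises(SimulationError):
            SimParams(q3=1.5)
        with pytest.raises(SimulationError):
            SimParams(ssd_rate=-1)

    def test_truth_labels_recovered_by_rigid_classification(self, rigid):
        params = SimParams(q3=0.55, q4=0.5, ssd_rate=0.4, seed=4)
        sims = sim_families(500, params)
        agree = total = 0
        for tree, truth in sims:
            fam = rigid.classify_family(tree)
            counts = fam.counts()
            total += 1
            ok = (counts.get("3R", 0) == int(truth.three_r)
                  and counts.get("4R", 0) == truth.n_4r_true
                  and counts.get("post3R_pre4R", 0)
                  == sum(r["retained"] for r in truth.between)
                  and counts.get("post4R", 0)
                  == sum(r["retained"] for r in truth.post4r))
            agree += ok
        assert agree / total >= 0.99

    def test_nni_noise_marks_low_support(self):
        params = SimParams(q3=1.0, q4=1.0, ssd_rate=0.0, topo_noise=1.0, seed=5)
        tree, truth = sim_families(1, params)[0]
        assert truth.noise_applied
        supports = [n.support for n in tree.root.preorder()
                    if not n.is_leaf and n.parent is not None]
        assert min(supports) == params.noise_support
        assert max(supports) == params.base_support


class TestInteractionSimulator:
    def test_independence(self):
        iset, retained = sim_interactions(2000, SimParams(partner_rho=0.0, seed=0))
        flags = np.array([[retained[min(p)], retained[max(p)]] for p in iset.pairs])
        corr = np.corrcoef(flags[:, 0], flags[:, 1])[0, 1]
        assert abs(corr) < 3 / math.sqrt(len(flags))

    def test_comonotone(self):
        iset, retained = sim_interactions(500, SimParams(partner_rho=1.0, seed=1))
        for pair in iset.pairs:
            a, b = tuple(pair)
            assert retained[a] == retained[b]

    def test_target_correlation(self):
        iset, retained = sim_interactions(2000, SimParams(partner_rho=0.5, seed=2))
        flags = np.array([[retained[min(p)], retained[max(p)]] for p in iset.pairs])
        corr = np.corrcoef(flags[:, 0], flags[:, 1])[0, 1]
        assert abs(corr - 0.5) < 3 / math.sqrt(len(flags))

    def test_infeasible_marginal_rejected(self):
        with pytest.raises(SimulationError):
            sim_interactions(10, SimParams(seed=0), marginal=1.0)


class TestTripletSimulator:
    def test_reproducibility(self):
        a = sim_triplets(ExprSimParams(seed=7), 50)
        b = sim_triplets(ExprSimParams(seed=7), 50)
        assert a[0].equals(b[0]) and a[1].equals(b[1]) and a[3] == b[3]

    def test_noiseless_conserved_duplicates_identical(self):
        dup, og, table, truth = sim_triplets(
            ExprSimParams(class_mix=(1.0, 0.0, 0.0), noise_sd=0.0, seed=8), 20)
        for row in table.itertuples(index=False):
            d1 = dup.loc[row.dup1].to_numpy()
            d2 = dup.loc[row.dup2].to_numpy()
            o = og.loc[row.outgroup_ortholog].to_numpy()
            assert np.allclose(d1, o) and np.allclose(d2, o)

    def test_noiseless_sub_sum_restores_ancestral_pattern(self):
        dup, og, table, truth = sim_triplets(
            ExprSimParams(class_mix=(0.0, 0.0, 1.0), noise_sd=0.0, seed=9), 50)
        for row in table.itertuples(index=False):
            d1 = dup.loc[row.dup1].to_numpy()
            d2 = dup.loc[row.dup2].to_numpy()
            o = og.loc[row.outgroup_ortholog].to_numpy()
            # complementary partition: each tissue expressed by exactly one copy
            assert ((d1 > 0) ^ (d2 > 0)).sum() == 13
            r = np.corrcoef(d1 + d2, o)[0, 1]
            assert r > 0.553  # two-sided p < 0.03 at 15 tissues

    def test_mix_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            ExprSimParams(class_mix=(0.5, 0.2, 0.1))
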