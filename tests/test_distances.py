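import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import TreeNode

from phylosym.containers import FeatureTable
from phylosym import distances as dist


def _table(counts, asvs, samples):
    return FeatureTable(pd.DataFrame(counts, index=asvs, columns=samples))


class TestJaccard:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ([1, 1, 1, 0], [1, 1, 1, 0], 0.0),  # identical presence sets
            ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),  # disjoint
            ([1, 1, 1, 0], [0, 1, 1, 1], 0.5),  # |shared|=2, |union|=4
        ],
    )
    def test_known_values(self, s1, s2, expected):
        table = _table(np.array([s1, s2]).T, list("abcd"), ["S1", "S2"])
        assert dist.jaccard_matrix(table)["S1", "S2"] == pytest.approx(expected)

    def test_all_zero_sample_rejected(self):
        table = _table([[1, 0], [1, 0]], ["a", "b"], ["S1", "S2"])
        with pytest.raises(ValueError, match="all-zero"):
            dist.jaccard_matrix(table)

    def test_binarization_invariance(self, sim_small):
        table = sim_small.table
        scaled = FeatureTable(table.data * 7)
        np.testing.assert_allclose(
            dist.jaccard_matrix(table).data, dist.jaccard_matrix(scaled).data
        )


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([50.0, 50.0], [50.0, 50.0], 0.0),
            ([100.0, 0.0], [0.0, 100.0], 1.0),
            ([50.0, 50.0], [100.0, 0.0], 0.5),
        ],
    )
    def test_known_values(self, x, y, expected):
        vec = pd.DataFrame([x, y], index=["u", "v"])
        assert dist.braycurtis_matrix(vec)["u", "v"] == pytest.approx(expected)

    def test_zero_sum_vector_rejected(self):
        vec = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["u", "v"])
        with pytest.raises(ValueError, match="zero-sum"):
            dist.braycurtis_matrix(vec)


def _brute_force_unifrac(tree, table):
    """Independent oracle: enumerate every branch, test descendant presence."""
    presence = {s: {a for a in table.asv_ids if table.data.loc[a, s] > 0} for s in table.sample_ids}
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    for i, si in enumerate(table.sample_ids):
        for j, sj in enumerate(table.sample_ids):
            if j <= i:
                continue
            shared = union = 0.0
            for node in tree.traverse(include_self=False):
                tips = {t.name for t in node.tips(include_self=True)}
                in_i = bool(tips & presence[si])
                in_j = bool(tips & presence[sj])
                length = node.length or 0.0
                if in_i or in_j:
                    union += length
                if in_i and in_j:
                    shared += length
            out[i, j] = out[j, i] = 1.0 - shared / union
    return out


class TestUnweightedUnifrac:
    def test_partial_overlap_example(self, four_tip_tree):
        # S1={A}, S2={A,B}: shared edges {A, AB-stem} = 2; union = 3
        table = _table([[1, 1], [0, 1], [0, 0], [0, 0]], list("ABCD"), ["S1", "S2"])
        assert dist.unweighted_unifrac_matrix(table, four_tip_tree)["S1", "S2"] == pytest.approx(1 / 3)

    def test_disjoint_clades_give_one(self, four_tip_tree):
        table = _table([[1, 0], [1, 0], [0, 1], [0, 1]], list("ABCD"), ["S1", "S2"])
        assert dist.unweighted_unifrac_matrix(table, four_tip_tree)["S1", "S2"] == pytest.approx(1.0)

    def test_identical_presence_gives_zero(self, four_tip_tree):
        table = _table([[3, 1], [0, 0], [2, 9], [0, 0]], list("ABCD"), ["S1", "S2"])
        assert dist.unweighted_unifrac_matrix(table, four_tip_tree)["S1", "S2"] == pytest.approx(0.0)

    def test_missing_asv_listed(self, four_tip_tree):
        table = _table([[1, 1], [1, 1]], ["A", "zzz"], ["S1", "S2"])
        with pytest.raises(ValueError, match="zzz"):
            dist.unweighted_unifrac_matrix(table, four_tip_tree)

    def test_matches_brute_force_oracle_on_random_instances(self):
        from phylosym.simulate import SimConfig, sim_microbial_tree

        rng = np.random.default_rng(2024)
        for trial in range(100):
            n_tips = int(rng.integers(4, 17))
            cfg = SimConfig(n_asvs=n_tips, seed=int(rng.integers(2**31)))
            tree = sim_microbial_tree(cfg)
            asvs = [t.name for t in tree.tips()]
            n_samples = int(rng.integers(2, 5))
            pres = rng.integers(0, 2, size=(n_tips, n_samples))
            pres[rng.integers(n_tips), pres.sum(axis=0) == 0] = 1  # no empty sample
            table = _table(pres, asvs, [f"S{k}" for k in range(n_samples)])
            got = dist.unweighted_unifrac_matrix(table, tree)
            want = _brute_force_unifrac(tree, table)
            np.testing.assert_allclose(got.data, want, atol=1e-12)

    def test_star_tree_unifrac_equals_jaccard(self):
        rng = np.random.default_rng(5)
        n = 10
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        star = TreeNode.read(io.StringIO(newick))
        pres = rng.integers(0, 2, size=(n, 4))
        pres[0, pres.sum(axis=0) == 0] = 1
        table = _table(pres, [f"t{i}" for i in range(n)], list("wxyz"))
        np.testing.assert_allclose(
            dist.unweighted_unifrac_matrix(table, star).data,
            dist.jaccard_matrix(table).data,
            atol=1e-12,
        )

    def test_agrees_with_skbio_reference(self, sim_small):
        from skbio.diversity import beta_diversity

        table = sim_small.table
        ref = beta_diversity(
            "unweighted_unifrac",
            table.counts.T,
            ids=table.sample_ids,
            taxa=table.asv_ids,
            tree=sim_small.microbial_tree,
        )
        got = dist.unweighted_unifrac_matrix(table, sim_small.microbial_tree)
        np.testing.assert_allclose(got.data, ref.data, atol=1e-10)


class TestPatristic:
    def test_path_sums(self):
        tree = TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))
        dm = dist.patristic_matrix(tree)
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(4.0)
        assert dm["A", "A"] == 0.0

    def test_unknown_tip_errors(self, four_tip_tree):
        with pytest.raises(ValueError, match="nope"):
            dist.patristic_matrix(four_tip_tree, ["A", "nope"])


class TestAlphaDiversity:
    def test_uniform_shannon_and_observed(self):
        table = _table([[5], [5], [5], [5]], list("abcd"), ["S1"])
        assert dist.alpha_diversity(table, "shannon")["S1"] == pytest.approx(np.log(4))
        assert dist.alpha_diversity(table, "observed")["S1"] == 4
        assert dist.alpha_diversity(table, "pielou")["S1"] == pytest.approx(1.0)

    def test_single_asv_sample(self):
        table = _table([[9], [0]], ["a", "b"], ["S1"])
        assert dist.alpha_diversity(table, "observed")["S1"] == 1
        assert dist.alpha_diversity(table, "shannon")["S1"] == pytest.approx(0.0)

    def test_faith_pd_root_inclusive(self, four_tip_tree):
        table = _table([[1], [1], [0], [0]], list("ABCD"), ["S1"])
        assert dist.alpha_diversity(table, "faith_pd", tree=four_tip_tree)["S1"] == pytest.approx(3.0)

    def test_faith_pd_requires_tree(self, small_table):
        with pytest.raises(ValueError, match="tree"):
            dist.alpha_diversity(small_table, "faith_pd")

    def test_faith_pd_agrees_with_skbio(self, sim_small):
        from skbio.diversity.alpha import faith_pd

        table = sim_small.table
        got = dist.alpha_diversity(table, "faith_pd", tree=sim_small.microbial_tree)
        for s in table.sample_ids[:5]:
            want = faith_pd(
                table.data[s].to_numpy(), taxa=table.asv_ids, tree=sim_small.microbial_tree
            )
            assert got[s] == pytest.approx(want, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_distance_matrix_invariants_hold_on_random_tables(seed):
    """Zero diagonal, symmetry, range bounds for Jaccard/UniFrac."""
    from phylosym.simulate import SimConfig, simulate

    cfg = SimConfig(n_species=6, n_orders=2, n_asvs=20, samples_per_species=1, reads_per_sample=100, seed=seed)
    sim = simulate(cfg)
    for dm in (
        dist.jaccard_matrix(sim.table),
        dist.unweighted_unifrac_matrix(sim.table, sim.microbial_tree),
    ):
        assert np.all(np.diag(dm.data) == 0)
        np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-12)
        assert dm.data.min() >= 0 and dm.data.max() <= 1
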