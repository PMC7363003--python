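import itertools

import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.assembly import classify_pair
from conftest import random_table


def brute_force_beta_mntd(pk: dict, pl: dict, dist: pd.DataFrame) -> float:
    """Independent double-loop implementation of the abundance-weighted
    β-mean nearest taxon distance."""
    total = 0.0
    for i, p in pk.items():
        total += p * min(dist.loc[i, j] for j in pl)
    for j, p in pl.items():
        total += p * min(dist.loc[j, i] for i in pk)
    return 0.5 * total


class TestCophenetic:
    def test_three_tip_path_sums(self, three_tip_tree):
        d = ea.cophenetic_distances(three_tip_tree).to_frame()
        assert d.loc["A", "B"] == 2.0
        assert d.loc["A", "C"] == 4.0
        assert d.loc["B", "C"] == 4.0
        assert np.diag(d.to_numpy()).sum() == 0.0

    def test_balanced_ultrametric_cross_cherry_distances_equal(self):
        import io as _io
        from skbio import TreeNode
        tree = TreeNode.read(_io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
        d = ea.cophenetic_distances(tree).to_frame()
        cross = [d.loc[i, j] for i in "AB" for j in "CD"]
        assert len(set(cross)) == 1


class TestBetaMNTD:
    def test_hand_computed_examples(self, three_tip_tree):
        d = ea.cophenetic_distances(three_tip_tree)
        assert ea.beta_mntd(pd.Series({"A": 0.5, "B": 0.5}),
                            pd.Series({"C": 1.0}), d) == pytest.approx(4.0)
        assert ea.beta_mntd(pd.Series({"A": 1.0}),
                            pd.Series({"B": 1.0}), d) == pytest.approx(2.0)
        assert ea.beta_mntd(pd.Series({"A": 0.5, "B": 0.5}),
                            pd.Series({"A": 0.5, "B": 0.5}), d) == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n_otus = int(rng.integers(3, 9))
            n_samples = int(rng.integers(2, 5))
            tree = ea.simulate_tree(n_otus, seed=int(rng.integers(1 << 30)))
            d = ea.cophenetic_distances(tree)
            table = random_table(rng, n_otus, n_samples)
            table = ea.CommunityTable(
                table.counts.set_axis(list(d.ids), axis=0))
            props = ea.relative_abundance(table)
            mat = ea.beta_mntd_matrix(table, d)
            for k, l in itertools.combinations(range(n_samples), 2):
                pk = props.iloc[:, k]
                pl = props.iloc[:, l]
                expected = brute_force_beta_mntd(
                    pk[pk > 0].to_dict(), pl[pl > 0].to_dict(), d.to_frame())
                assert mat.values[k, l] == pytest.approx(expected,
                                                         abs=1e-12)
            np.testing.assert_allclose(mat.values, mat.values.T)
            assert (mat.values >= -1e-12).all()

    def test_empty_support_rejected(self, three_tip_tree):
        d = ea.cophenetic_distances(three_tip_tree)
        with pytest.raises(ValueError, match="empty|sum"):
            ea.beta_mntd(pd.Series({"A": 0.0}), pd.Series({"B": 1.0}), d)


class TestBetaNTI:
    def test_relabeling_invariance(self):
        """Renaming tips consistently in table and tree changes nothing."""
        tree = ea.simulate_tree(12, seed=5)
        d = ea.cophenetic_distances(tree)
        rng = np.random.default_rng(6)
        table = random_table(rng, 12, 4)
        table = ea.CommunityTable(table.counts.set_axis(list(d.ids), axis=0))
        z1 = ea.beta_nti(table, d, n_null=49, seed=7)
        mapping = {o: f"tax_{i}" for i, o in enumerate(d.ids)}
        table2 = ea.CommunityTable(
            table.counts.rename(index=mapping))
        d2 = ea.DissimilarityMatrix(
            tuple(mapping[i] for i in d.ids), d.values.copy())
        z2 = ea.beta_nti(table2, d2, n_null=49, seed=7)
        np.testing.assert_allclose(z1.values, z2.values, equal_nan=True)

    def test_star_tree_degenerate_null_is_nan(self):
        import io as _io
        from skbio import TreeNode
        tree = TreeNode.read(_io.StringIO("(A:1,B:1,C:1,D:1);"))
        d = ea.cophenetic_distances(tree)
        table = ea.CommunityTable(pd.DataFrame(
            {"s1": [5, 5, 0, 0], "s2": [0, 0, 5, 5]},
            index=list(d.ids)))
        z = ea.beta_nti(table, d, n_null=30, seed=1)
        assert np.isnan(z.values[0, 1])

    def test_disjoint_clades_give_strong_positive_bnti(self):
        import io as _io
        from skbio import TreeNode
        left = ",".join(f"L{i}:0.1" for i in range(8))
        right = ",".join(f"R{i}:0.1" for i in range(8))
        tree = TreeNode.read(_io.StringIO(f"(({left}):5,({right}):5);"))
        d = ea.cophenetic_distances(tree)
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(0, index=list(d.ids),
                              columns=["s1", "s2"], dtype=int)
        for i in range(8):
            counts.loc[f"L{i}", "s1"] = rng.integers(5, 20)
            counts.loc[f"R{i}", "s2"] = rng.integers(5, 20)
        z = ea.beta_nti(ea.CommunityTable(counts), d, n_null=999, seed=3)
        assert z.values[0, 1] > 2.0

    def test_seed_reproducible(self):
        tree = ea.simulate_tree(10, seed=8)
        d = ea.cophenetic_distances(tree)
        rng = np.random.default_rng(9)
        table = random_table(rng, 10, 3)
        table = ea.CommunityTable(table.counts.set_axis(list(d.ids), axis=0))
        z1 = ea.beta_nti(table, d, n_null=49, seed=10)
        z2 = ea.beta_nti(table, d, n_null=49, seed=10)
        np.testing.assert_array_equal(z1.values, z2.values)

    def test_too_few_nulls_rejected(self, three_tip_tree):
        d = ea.cophenetic_distances(three_tip_tree)
        table = ea.CommunityTable(pd.DataFrame(
            {"s1": [1, 0, 0], "s2": [0, 1, 0]}, index=list(d.ids)))
        with pytest.raises(ValueError):
            ea.beta_nti(table, d, n_null=1, seed=0)


class TestRaupCrick:
    def test_shared_single_otu_pool_gives_zero(self):
        # the pool is one OTU: every null equals the observed communities,
        # so the ties formula lands exactly on 0
        table = ea.CommunityTable(pd.DataFrame(
            {"s1": [10], "s2": [10]}, index=["a"]))
        rc = ea.raup_crick_bray(table, n_null=99, seed=0)
        assert rc.values[0, 1] == 0.0

    def test_extreme_divergence_gives_plus_one(self):
        # both samples contain both OTUs, but with opposite extreme
        # abundances; null fills are near-even, so BC_obs beats every null
        table = ea.CommunityTable(pd.DataFrame(
            {"s1": [99, 1], "s2": [1, 99]}, index=["a", "b"]))
        rc = ea.raup_crick_bray(table, n_null=999, seed=1)
        assert rc.values[0, 1] == 1.0

    def test_constructed_null_boundaries_exact(self):
        """Observation above/below/equal to every null value hits the
        boundaries of the ties formula exactly."""
        null = np.linspace(0.2, 0.6, 999)
        assert ea.raup_crick_score(0.9, null) == 1.0
        assert ea.raup_crick_score(0.1, null) == -1.0
        assert ea.raup_crick_score(0.3, np.full(999, 0.3)) == 0.0
        # sign flips around the null median
        lo, hi = np.quantile(null, [0.25, 0.75])
        assert ea.raup_crick_score(hi, null) == -ea.raup_crick_score(lo, null)

    def test_identical_samples_strongly_negative(self):
        # identical compositions over a 3-OTU pool: observed BC = 0,
        # membership lotteries make almost every null pair dissimilar
        table = ea.CommunityTable(pd.DataFrame(
            {"s1": [50, 50, 2], "s2": [50, 50, 2]}, index=["a", "b", "c"]))
        rc = ea.raup_crick_bray(table, n_null=999, seed=2)
        assert rc.values[0, 1] < -0.95

    def test_bounds_and_symmetry_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = random_table(rng, 12, 4, max_count=30)
            rc = ea.raup_crick_bray(t, n_null=99,
                                    seed=int(rng.integers(1 << 30)))
            assert (rc.values >= -1.0).all() and (rc.values <= 1.0).all()
            np.testing.assert_allclose(rc.values, rc.values.T)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        t = random_table(rng, 10, 3)
        a = ea.raup_crick_bray(t, n_null=49, seed=5)
        b = ea.raup_crick_bray(t, n_null=49, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestPartition:
    @pytest.mark.parametrize("bnti,rc,label", [
        (3.0, 0.0, "heterogeneous_selection"),
        (-2.5, 0.0, "homogeneous_selection"),
        (1.0, 0.99, "dispersal_limitation"),
        (0.5, 0.1, "undominated"),
        (0.0, -0.99, "homogenizing_dispersal"),
        # boundary values fall to the stochastic/undominated side
        (2.0, 0.0, "undominated"),
        (-2.0, 0.96, "dispersal_limitation"),
        (0.0, 0.95, "undominated"),
        (0.0, -0.95, "undominated"),
    ])
    def test_threshold_mapping(self, bnti, rc, label):
        assert classify_pair(bnti, rc) == label

    def _matrices(self, values, ids):
        n = len(ids)
        m = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        m[iu] = values
        m += m.T
        return ea.DissimilarityMatrix(tuple(ids), m)

    def test_fractions_partition_and_sum_to_one(self):
        ids = ["s1", "s2", "s3", "s4"]
        bnti = self._matrices([3.0, -2.5, 1.0, 0.5, 0.0, 1.2], ids)
        rc = self._matrices([0.0, 0.0, 0.99, 0.1, -0.99, 0.3], ids)
        design = ea.EnvironmentDesign(pd.DataFrame(
            {"environment": ["E1", "E1", "E2", "E2"]}, index=ids))
        summary = ea.partition_processes(bnti, rc, design, grouping="all")
        fr = summary.fractions.loc["all"]
        assert fr["n_pairs"] == 6
        assert sum(fr[lab] for lab in
                   ea.assembly.PROCESS_LABELS) == pytest.approx(1.0)
        assert fr["deterministic"] + fr["stochastic"] == pytest.approx(1.0)
        assert fr["heterogeneous_selection"] == pytest.approx(1 / 6)
        assert fr["dispersal_limitation"] == pytest.approx(1 / 6)

    def test_nan_pairs_excluded_with_count(self, caplog):
        ids = ["s1", "s2", "s3"]
        bnti = self._matrices([np.nan, 3.0, 0.0], ids)
        rc = self._matrices([0.0, 0.0, 0.0], ids)
        design = ea.EnvironmentDesign(pd.DataFrame(
            {"environment": ["E", "E", "E"]}, index=ids))
        summary = ea.partition_processes(bnti, rc, design, grouping="all")
        assert summary.fractions.loc["all", "n_pairs"] == 2

    def test_grouped_pairs_require_shared_group(self):
        ids = ["s1", "s2", "s3", "s4"]
        bnti = self._matrices([3.0] * 6, ids)
        rc = self._matrices([0.0] * 6, ids)
        design = ea.EnvironmentDesign(pd.DataFrame(
            {"environment": ["E1", "E1", "E2", "E2"],
             "treatment": ["t", "t", "t", "u"]}, index=ids))
        by_env = ea.partition_processes(bnti, rc, design,
                                        grouping="environment")
        assert by_env.fractions["n_pairs"].to_dict() == {"E1": 1, "E2": 1}
        by_trt = ea.partition_processes(bnti, rc, design,
                                        grouping="treatment")
        assert by_trt.fractions.loc["t", "n_pairs"] == 3
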