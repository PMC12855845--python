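"""Phylogenetic binning, beta-NRI / Raup-Crick nulls and process partition."""


import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rhizoecol import assembly, simulate
from rhizoecol.assembly import PhyloBin
from .conftest import make_table


def tree_from(newick: str) -> TreeNode:
    return TreeNode.read([newick], convert_underscores=False)


class TestPhyloBins:
    def test_star_tree_single_bin(self):
        tree = tree_from("(A:1,B:1,C:1,D:1);")
        bins = assembly.phylo_bins(tree, ds=3.0, min_size=2)
        assert len(bins) == 1
        assert sorted(bins[0].taxa) == ["A", "B", "C", "D"]

    def test_two_distant_clades_two_bins(self):
        tree = tree_from("((A:0.01,B:0.01):5,(C:0.01,D:0.01):5);")
        bins = assembly.phylo_bins(tree, ds=0.2, min_size=2)
        assert sorted(sorted(b.taxa) for b in bins) == [["A", "B"], ["C", "D"]]

    def test_bins_partition_taxa(self):
        tree = simulate.simulate_tree([f"x{i}" for i in range(100)], seed=1)
        bins = assembly.phylo_bins(tree, ds=0.2, min_size=10)
        all_taxa = [t for b in bins for t in b.taxa]
        assert sorted(all_taxa) == sorted(f"x{i}" for i in range(100))
        assert all(len(b.taxa) >= 10 for b in bins)

    def test_tiny_taxon_set_falls_back_to_one_bin(self):
        tree = tree_from("(A:1,B:1);")
        with pytest.warns(UserWarning):
            bins = assembly.phylo_bins(tree, ds=0.1, min_size=24)
        assert len(bins) == 1


class TestBetaMPD:
    # distances: d(A,B)=2, d(A,C)=4, d(B,C)=6
    TREE = "((A:0,B:2):2,C:2);"

    def test_hand_worked_value(self):
        tree = tree_from(self.TREE)
        table = make_table([[2, 2, 0], [0, 1, 3]], taxa=["A", "B", "C"])
        bin_ = PhyloBin(0, ["A", "B", "C"])
        # wx=(.5,.5,0), wy=(0,.25,.75):
        # .5*.25*2 + .5*.75*4 + .5*.75*6 = 4.0
        val = assembly.beta_mpd("s0", "s1", bin_, table, tree)
        assert val == pytest.approx(4.0)

    def test_self_comparison_equals_within_mpd(self):
        tree = tree_from(self.TREE)
        table = make_table([[1, 2, 3], [1, 2, 3]], taxa=["A", "B", "C"])
        bin_ = PhyloBin(0, ["A", "B", "C"])
        w = np.array([1, 2, 3]) / 6
        d = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        assert assembly.beta_mpd("s0", "s1", bin_, table, tree) == pytest.approx(
            float(w @ d @ w)
        )

    def test_constant_distances_ignore_abundances(self):
        tree = tree_from("(A:1,B:1,C:1);")  # all pairwise distances = 2
        bin_ = PhyloBin(0, ["A", "B", "C"])
        for counts in ([[9, 1, 1], [1, 1, 9]], [[1, 1, 1], [5, 5, 5]]):
            table = make_table(counts, taxa=["A", "B", "C"])
            val = assembly.beta_mpd("s0", "s1", bin_, table, tree)
            # disjoint-support-free comparison: expected constant minus the
            # diagonal contribution sum(wx*wy)*2
            wx = np.array(counts[0]) / sum(counts[0])
            wy = np.array(counts[1]) / sum(counts[1])
            assert val == pytest.approx(2 * (1 - wx @ wy))

    def test_empty_bin_rejected(self):
        tree = tree_from(self.TREE)
        table = make_table([[0, 0, 5], [1, 1, 1]], taxa=["A", "B", "C"])
        with pytest.raises(ValueError):
            assembly.beta_mpd("s0", "s1", PhyloBin(0, ["A", "B"]), table, tree)


class TestBNRI:
    def test_zero_variance_null_gives_zero(self):
        tree = tree_from("(A:1,B:1,C:1);")  # shuffling tips changes nothing
        table = make_table([[3, 2, 1], [1, 2, 3]], taxa=["A", "B", "C"])
        with pytest.warns(UserWarning):
            z = assembly.bnri("s0", "s1", PhyloBin(0, ["A", "B", "C"]), table, tree, 49, seed=0)
        assert z == 0.0

    def test_deterministic_given_seed(self, neutral_community):
        _, table, tree, _ = neutral_community
        bin_ = PhyloBin(0, table.taxon_ids[:20])
        a = assembly.bnri("S001", "S002", bin_, table, tree, 99, seed=3)
        b = assembly.bnri("S001", "S002", bin_, table, tree, 99, seed=3)
        assert a == b

    def test_relabelling_invariance(self, neutral_community):
        """Renaming taxa (tree tips and table columns together) is a no-op."""
        _, table, tree, _ = neutral_community
        bin_ = PhyloBin(0, table.taxon_ids[:15])
        z1 = assembly.bnri("S001", "S002", bin_, table, tree, 99, seed=4)
        mapping = {t: f"renamed_{i}" for i, t in enumerate(table.taxon_ids)}
        tree2 = tree.copy()
        for tip in tree2.tips():
            tip.name = mapping[tip.name]
        counts2 = table.counts.rename(columns=mapping)
        table2 = make_table(counts2.to_numpy(), samples=list(counts2.index), taxa=list(counts2.columns))
        bin2 = PhyloBin(0, [mapping[t] for t in bin_.taxa])
        z2 = assembly.bnri("S001", "S002", bin2, table2, tree2, 99, seed=4)
        assert z1 == pytest.approx(z2, abs=1e-12)


class TestRCBray:
    def test_identical_samples_hit_lower_boundary(self):
        rng = np.random.default_rng(0)
        row = rng.integers(5, 40, size=25)
        counts = np.vstack([row, row] + [rng.integers(0, 40, size=25) for _ in range(6)])
        table = make_table(counts)
        rc = assembly.rc_bray("s0", "s1", PhyloBin(0, list(table.taxon_ids)), table, 99, seed=1)
        assert rc == -1.0

    def test_disjoint_samples_hit_upper_boundary(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 20, size=(8, 20))
        counts[0, 10:] = 0
        counts[1, :10] = 0
        table = make_table(counts)
        rc = assembly.rc_bray("s0", "s1", PhyloBin(0, list(table.taxon_ids)), table, 99, seed=3)
        assert rc == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.integers(0, 30, size=(6, 15)) + 1)
        bin_ = PhyloBin(0, list(table.taxon_ids))
        assert assembly.rc_bray("s0", "s3", bin_, table, 99, seed=5) == assembly.rc_bray(
            "s0", "s3", bin_, table, 99, seed=5
        )


class TestClassify:
    @pytest.mark.parametrize(
        "z,rc,expected",
        [
            (2.5, 0.0, "HeS"),
            (-2.5, 0.0, "HoS"),
            (0.0, 0.99, "DL"),
            (0.0, -0.99, "HD"),
            (0.0, 0.0, "DR"),
            (1.96, 0.99, "DL"),  # boundary: selection needs strict excess
            (-1.96, -0.99, "HD"),
        ],
    )
    def test_examples(self, z, rc, expected):
        assert assembly.classify_process(z, rc) == expected

    def test_truth_table_grid(self):
        """Exhaustive comparison with an independent rule-order oracle."""
        for z in np.linspace(-4, 4, 21):
            for rc in np.linspace(-1, 1, 21):
                if z > 1.96:
                    want = "HeS"
                elif z < -1.96:
                    want = "HoS"
                elif rc > 0.95:
                    want = "DL"
                elif rc < -0.95:
                    want = "HD"
                else:
                    want = "DR"
                assert assembly.classify_process(z, rc) == want

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            assembly.classify_process(float("nan"), 0.0)


class TestPartition:
    def test_identical_samples_give_pure_homogenising_signal(self):
        """All-identical communities sit below every stochastic null, so each
        pair-bin lands in HD and the aggregation yields a single process."""
        rng = np.random.default_rng(6)
        row = rng.integers(5, 30, size=30)
        table = make_table(np.tile(row, (6, 1)))
        # star tree: the taxa-shuffle null is degenerate, so beta-NRI = 0 and
        # the classification is decided by RC alone
        tree = tree_from("(" + ",".join(f"{t}:1" for t in table.taxon_ids) + ");")
        md = pd.Series(["g"] * 6, index=table.sample_ids)
        part = assembly.partition_assembly(table, tree, md, n_null=49, seed=8, min_size=30)
        assert part.fractions.loc["g", "HD"] == pytest.approx(1.0)
        assert part.fractions.loc["g"].sum() == pytest.approx(1.0)

    def test_fractions_and_weights_normalised(self, neutral_community):
        _, table, tree, metadata = neutral_community
        part = assembly.partition_assembly(table, tree, metadata, n_null=49, seed=9, min_size=20)
        assert np.allclose(part.fractions.sum(axis=1), 1.0, atol=1e-9)
        weight_sums = part.pair_calls.groupby(["group", "sample_x", "sample_y"])["weight"].sum()
        assert np.allclose(weight_sums, 1.0, atol=1e-9)

    def test_neutral_data_is_drift_dominated(self, neutral_community):
        _, table, tree, metadata = neutral_community
        part = assembly.partition_assembly(table, tree, metadata, n_null=99, seed=10, min_size=20)
        assert part.fractions.loc["overall", "DR"] > 0.5
        stochastic = part.fractions.loc["overall", ["DL", "HD", "DR"]].sum()
        assert stochastic >= 0.8
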