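"""Alpha/beta diversity closed forms, ordination geometry, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import permanova as skbio_permanova

from rhizoecol import diversity
from .conftest import make_table


class TestAlpha:
    def test_closed_forms(self):
        table = make_table([[4, 4, 0, 0], [1, 1, 2, 5], [7, 0, 0, 0]])
        out = diversity.alpha_diversity(table)
        assert out.loc["s0", "richness"] == 2
        assert out.loc["s0", "shannon"] == pytest.approx(np.log(2))
        # F1=2, F2=1 -> chao1 = 4 + 2*1/(2*2) = 4.5
        assert out.loc["s1", "chao1"] == pytest.approx(4.5)
        assert out.loc["s2", "shannon"] == 0.0

    def test_empty_sample_warns_and_zeroes(self):
        table = make_table([[0, 0], [1, 1]])
        with pytest.warns(UserWarning):
            out = diversity.alpha_diversity(table)
        assert (out.loc["s0"] == 0).all()


class TestBrayCurtis:
    def test_boundary_values(self):
        table = make_table([[1, 1, 0], [0, 1, 1], [1, 1, 0], [2, 0, 0], [0, 0, 5]])
        dm = diversity.bray_curtis(table)
        assert dm["s0", "s1"] == pytest.approx(0.5)  # 2/4 by hand
        assert dm["s0", "s2"] == 0.0
        assert dm["s3", "s4"] == 1.0  # disjoint supports

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=(12, 18)) + (rng.random((12, 18)) < 0.1)
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = make_table(counts)
        dm = diversity.bray_curtis(table)
        for i in range(12):
            for j in range(12):
                x, y = counts[i].astype(float), counts[j].astype(float)
                expected = np.abs(x - y).sum() / (x + y).sum()
                assert dm[f"s{i}", f"s{j}"] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            diversity.bray_curtis(make_table([[0, 0], [1, 1]]))


class TestPCoA:
    def test_reconstructs_planar_euclidean_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        dm_mat = squareform(pdist(pts))
        from skbio import DistanceMatrix

        res = diversity.pcoa(DistanceMatrix(dm_mat, ids=list("abcde")))
        coords = res.samples.to_numpy()[:, :2]
        rec = squareform(pdist(coords))
        assert np.abs(rec - dm_mat).max() < 1e-8

    def test_collinear_points_one_axis(self):
        from skbio import DistanceMatrix

        d = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        res = diversity.pcoa(DistanceMatrix(d, ids=list("abc")))
        pos = res.eigvals[res.eigvals > 1e-12]
        assert res.eigvals.iloc[0] / pos.sum() == pytest.approx(1.0, abs=1e-9)

    def test_proportions_bounded(self, neutral_community):
        _, table, _, _ = neutral_community
        res = diversity.pcoa(diversity.bray_curtis(table))
        pos = res.proportion_explained[res.eigvals > 0]
        assert pos.sum() <= 1 + 1e-9
        assert (np.diff(pos.to_numpy()) <= 1e-12).all()


class TestPermanova:
    def test_matches_skbio_statistic(self, neutral_community):
        _, table, _, metadata = neutral_community
        dm = diversity.bray_curtis(table)
        mine = diversity.permanova(dm, metadata, n_permutations=49, seed=0)
        ref = skbio_permanova(dm, metadata.loc[list(dm.ids)].values, permutations=9)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_f_invariant_under_sample_reordering(self, neutral_community):
        _, table, _, metadata = neutral_community
        dm = diversity.bray_curtis(table)
        rng = np.random.default_rng(2)
        order = list(rng.permutation(list(dm.ids)))
        dm2 = dm.filter(order)
        a = diversity.permanova(dm, metadata, 19, seed=0)
        b = diversity.permanova(dm2, metadata, 19, seed=0)
        assert a.pseudo_f == pytest.approx(b.pseudo_f, abs=1e-12)

    def test_p_floor_and_determinism(self, neutral_community):
        _, table, _, metadata = neutral_community
        dm = diversity.bray_curtis(table)
        a = diversity.permanova(dm, metadata, 99, seed=5)
        b = diversity.permanova(dm, metadata, 99, seed=5)
        assert a.p_value == b.p_value
        assert a.p_value >= 1 / 100

    def test_r2_grows_with_separation(self):
        rng = np.random.default_rng(3)
        base = rng.integers(5, 40, size=(16, 12))
        shifted = base.copy()
        shifted[8:, :4] += 200
        md = pd.Series(["a"] * 8 + ["b"] * 8, index=[f"s{i}" for i in range(16)])
        r2 = {}
        for name, counts in (("null", base), ("shift", shifted)):
            dm = diversity.bray_curtis(make_table(counts))
            r2[name] = diversity.permanova(dm, md, 19, seed=0).r2
        assert r2["shift"] > r2["null"]

    def test_small_group_rejected(self):
        table = make_table([[1, 2], [2, 1], [3, 1]])
        md = pd.Series(["a", "a", "b"], index=table.sample_ids)
        with pytest.raises(ValueError):
            diversity.permanova(diversity.bray_curtis(table), md)


class TestSimilarityContrast:
    def test_set_combinatorics_partition(self, neutral_community):
        _, table, _, _ = neutral_community
        md = pd.Series(
            ["MIX", "NSS", "SS", "TST"] * 4, index=table.sample_ids
        )
        dm = diversity.bray_curtis(table)
        sets, tests = diversity.similarity_contrast(dm, md)
        within = [s for s in sets.index if s.startswith("within")]
        between = [s for s in sets.index if s.startswith("between")]
        assert len(within) == 4 and len(between) == 6
        n = len(table.sample_ids)
        assert sets["n_pairs"].sum() == n * (n - 1) // 2
        assert len(tests) == 45  # all pairwise contrasts among 10 sets

    def test_identical_samples_all_similar(self):
        table = make_table(np.tile([3, 2, 1], (8, 1)))
        md = pd.Series(["a"] * 4 + ["b"] * 4, index=table.sample_ids)
        sets, tests = diversity.similarity_contrast(diversity.bray_curtis(table), md)
        assert (sets["median_similarity"] == 1.0).all()
        assert (tests["q"] > 0.05).all()

    def test_tight_group_has_highest_within_similarity(self):
        rng = np.random.default_rng(4)
        tight = np.tile(rng.integers(10, 30, 10), (5, 1)) + rng.integers(0, 2, (5, 10))
        diffuse = rng.integers(0, 60, size=(15, 10)) + 1
        table = make_table(np.vstack([tight, diffuse]))
        md = pd.Series(
            ["tight"] * 5 + ["d1"] * 5 + ["d2"] * 5 + ["d3"] * 5,
            index=table.sample_ids,
        )
        sets, _ = diversity.similarity_contrast(diversity.bray_curtis(table), md)
        within = sets[sets.index.str.startswith("within")]
        assert within["median_similarity"].idxmax() == "within:tight"


class TestAnovaTukey:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        vals = pd.Series(
            np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 10)]),
            index=[f"s{i}" for i in range(20)],
        )
        md = pd.Series(["a"] * 10 + ["b"] * 10, index=vals.index)
        out = diversity.anova_tukey(vals, md)
        assert out["p"] < 1e-6 and not out["degenerate"]
        assert (out["tukey"]["reject"] == True).all()  # noqa: E712

    def test_degenerate_flagged(self):
        vals = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        md = pd.Series(["a"] * 3 + ["b"] * 3, index=vals.index)
        with pytest.warns(UserWarning):
            out = diversity.anova_tukey(vals, md)
        assert out["degenerate"]

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_sim = 1000
        idx = [f"s{i}" for i in range(30)]
        md = pd.Series(np.repeat(["a", "b", "c"], 10), index=idx)
        for _ in range(n_sim):
            vals = pd.Series(rng.normal(size=30), index=idx)
            rejections += diversity.anova_tukey(vals, md)["p"] <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07
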