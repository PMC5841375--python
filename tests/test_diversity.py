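import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

import hybridotu as h
from hybridotu.diversity import _corr
from hybridotu.taxonomy import RANKS, parse_lineage

from test_phylotree import random_additive_tree


def table_from(counts, samples, otus):
    return h.OTUTable(pd.DataFrame(counts, index=samples, columns=otus))


class TestSubsample:
    def test_depth_and_bounds(self):
        t = table_from([[5, 5]], ["s1"], ["a", "b"])
        out = h.subsample_counts(t, 4, seed=0)
        assert out.counts.loc["s1"].sum() == 4
        assert (out.counts.values <= t.counts.values).all()

    def test_exact_depth_unchanged(self):
        t = table_from([[3, 5]], ["s1"], ["a", "b"])
        out = h.subsample_counts(t, 8, seed=0)
        assert out.counts.equals(t.counts)

    def test_shallow_sample_dropped_with_warning(self):
        t = table_from([[3, 1], [50, 50]], ["lo", "hi"], ["a", "b"])
        with pytest.warns(UserWarning, match="lo"):
            out = h.subsample_counts(t, 10, seed=0)
        assert out.sample_ids == ["hi"]

    def test_subsampled_proportions_unbiased(self):
        t = table_from([[600, 300, 100]], ["s1"], ["a", "b", "c"])
        means = np.zeros(3)
        for seed in range(300):
            means += h.subsample_counts(t, 100, seed=seed).counts.values[0]
        means /= 300
        # hypergeometric mean is depth * proportion; 3 MC SE tolerance
        se = np.sqrt(100 * 0.6 * 0.4 / 300)
        assert np.all(np.abs(means - [60, 30, 10]) < 3 * se * 2)


class TestBrayCurtis:
    def test_closed_form(self):
        t = table_from([[1, 2, 3], [3, 2, 1]], ["x", "y"], list("abc"))
        assert h.bray_curtis(t)["x", "y"] == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        t = table_from([[2, 2, 0, 0], [2, 2, 0, 0], [0, 0, 3, 3]],
                       ["x", "y", "z"], list("abcd"))
        d = h.bray_curtis(t)
        assert d["x", "y"] == 0.0
        assert d["x", "z"] == 1.0

    def test_all_zero_pair_is_zero_by_convention(self):
        t = table_from([[0, 0], [0, 0]], ["x", "y"], ["a", "b"])
        assert h.bray_curtis(t)["x", "y"] == 0.0


class TestUniFrac:
    def _toy(self):
        tree = TreeNode.read(["((A:1,B:1):1,C:2);"])
        t = table_from([[4, 0, 0], [0, 6, 0]], ["s1", "s2"], list("ABC"))
        return t, tree

    def test_toy_unweighted_value(self):
        t, tree = self._toy()
        d = h.unifrac(t, tree, weighted=False)
        assert d["s1", "s2"] == pytest.approx(2 / 3)

    def test_identical_communities_zero_both_variants(self):
        tree = TreeNode.read(["((A:1,B:1):1,C:2);"])
        t = table_from([[3, 2, 1], [3, 2, 1]], ["s1", "s2"], list("ABC"))
        for weighted in (False, True):
            assert h.unifrac(t, tree, weighted=weighted)["s1", "s2"] == 0.0

    def test_missing_otu_in_tree_is_hard_error(self):
        tree = TreeNode.read(["(A:1,B:1);"])
        t = table_from([[1, 1, 1], [1, 0, 1]], ["s1", "s2"], list("ABC"))
        with pytest.raises(ValueError, match="absent"):
            h.unifrac(t, tree, weighted=False)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_skbio_on_random_trees(self, weighted):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(2)
        for rep in range(5):
            tree, _ = random_additive_tree(10, rng)
            tree = h.midpoint_root(tree)
            otus = sorted(t.name for t in tree.tips())
            counts = rng.integers(0, 20, size=(4, 10))
            counts[0, :5] = 0  # exercise absent taxa
            t = table_from(counts, [f"s{i}" for i in range(4)], otus)
            mine = h.unifrac(t, tree, weighted=weighted, normalized=True)
            metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
            kwargs = {"normalized": True} if weighted else {}
            ref = beta_diversity(
                metric, counts, ids=t.sample_ids, taxa=otus, tree=tree, **kwargs
            )
            assert np.allclose(mine.data, ref.data, atol=1e-10)


class TestMantel:
    def _dm(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 3))
        D = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        return DistanceMatrix(D, [f"s{i}" for i in range(n)])

    def test_self_comparison_perfect(self):
        # n large enough that the identity permutation is never redrawn
        d = self._dm(n=12)
        res = h.mantel(d, d, n_perm=1000, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1001)

    def test_monotone_transform_spearman_invariant(self):
        d = self._dm(3)
        d2 = DistanceMatrix(d.data**2, d.ids)
        assert h.mantel(d, d2, n_perm=10, seed=0).r == pytest.approx(1.0)

    def test_matches_skbio_r(self):
        from skbio.stats.distance import mantel as sk_mantel

        for seed in range(5):
            d1, d2 = self._dm(seed), self._dm(seed + 100)
            mine = h.mantel(d1, d2, n_perm=0, seed=0)
            r, _, _ = sk_mantel(d1, d2, method="spearman", permutations=0)
            assert mine.r == pytest.approx(r, abs=1e-12)

    def test_label_alignment_not_order(self):
        d1 = self._dm(1)
        perm = list(d1.ids)[::-1]
        d2 = DistanceMatrix(d1.filter(perm).data, perm)
        assert h.mantel(d1, d2, n_perm=10, seed=0).r == pytest.approx(1.0)

    def test_label_mismatch_error(self):
        d1 = self._dm(1)
        d2 = DistanceMatrix(d1.data, [f"x{i}" for i in range(6)])
        with pytest.raises(ValueError, match="label"):
            h.mantel(d1, d2)

    def test_bootstrap_se_present_and_sane(self):
        d1, d2 = self._dm(2, n=12), self._dm(7, n=12)
        res = h.mantel(d1, d2, n_perm=10, n_boot=100, seed=5)
        assert res.bootstrap_se is not None
        assert 0 < res.bootstrap_se < 1

    def test_permutation_p_uniform_under_null(self):
        # p-values under independence should be roughly uniform
        rng = np.random.default_rng(0)
        ps = []
        for k in range(60):
            d1, d2 = self._dm(2 * k + 1, n=8), self._dm(2 * k + 2, n=8)
            ps.append(h.mantel(d1, d2, n_perm=99, seed=k).p)
        assert 0.25 < np.mean(ps) < 0.75


def icc_oracle(groups):
    """Two-loop one-way ANOVA ICC, written independently of the library."""
    N = sum(len(g) for g in groups)
    G = len(groups)
    grand = sum(x for g in groups for x in g) / N
    ssb = ssw = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ssb += len(g) * (m - grand) ** 2
        for x in g:
            ssw += (x - m) ** 2
    msb, msw = ssb / (G - 1), ssw / (N - G)
    k0 = (N - sum(len(g) ** 2 for g in groups) / N) / (G - 1)
    return (msb - msw) / (msb + (k0 - 1) * msw)


class TestICC:
    def _design(self, groups):
        entries = {}
        values = {}
        for gi, g in enumerate(groups):
            for ri, v in enumerate(g):
                sid = f"g{gi}r{ri}"
                entries[sid] = (f"subj{gi}", "c", ri)
                values[sid] = v
        return values, h.ReplicateDesign(entries)

    def test_zero_within_variance_gives_one(self):
        values, design = self._design([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        assert h.icc_oneway(values, design) == pytest.approx(1.0)

    def test_matches_two_loop_oracle_on_unbalanced_designs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            groups = [
                list(rng.normal(rng.normal(0, 2), 1, size=int(rng.integers(2, 5))))
                for _ in range(int(rng.integers(3, 8)))
            ]
            values, design = self._design(groups)
            assert h.icc_oneway(values, design) == pytest.approx(
                icc_oracle(groups), abs=1e-12
            )

    def test_matches_pingouin_icc1_on_balanced_design(self):
        import pingouin as pg

        rng = np.random.default_rng(9)
        groups = [list(rng.normal(rng.normal(0, 2), 1, size=3)) for _ in range(12)]
        values, design = self._design(groups)
        df = pd.DataFrame(
            [
                (f"t{gi}", f"j{ri}", v)
                for gi, g in enumerate(groups)
                for ri, v in enumerate(g)
            ],
            columns=["targets", "raters", "scores"],
        )
        icc1 = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        )
        icc1 = icc1.loc[icc1["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert h.icc_oneway(values, design) == pytest.approx(icc1, abs=1e-9)

    def test_single_replicate_groups_excluded_and_min_groups(self):
        values, design = self._design([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="2 groups"):
            h.icc_oneway(values, design)

    def test_null_simulation_near_zero(self):
        rng = np.random.default_rng(1)
        groups = [list(rng.normal(0, 1, 3)) for _ in range(200)]
        values, design = self._design(groups)
        assert abs(h.icc_oneway(values, design)) < 0.1


class TestPrevalenceAndCollapse:
    def test_strict_prevalence(self):
        counts = np.zeros((20, 2), dtype=int)
        counts[0, 0] = 5          # feature 'rare' in 1/20 samples
        counts[:, 1] = 1          # feature 'core' everywhere
        t = table_from(counts, [f"s{i}" for i in range(20)], ["rare", "core"])
        out = h.prevalence_filter(t, 0.10)
        assert out.otu_ids == ["core"]  # 1 <= 2 -> removed
        assert h.prevalence_filter(t, 0.90).otu_ids == ["core"]

    def test_per_taxon_spearman_examples(self):
        # g1's relative abundance rises across samples in both tables;
        # g2 is entirely absent from table a (zero-vector convention)
        a = table_from([[10, 90, 0], [20, 20, 0], [30, 5, 0]],
                       ["s1", "s2", "s3"], ["g1", "gx", "g2"])
        b = table_from([[1, 10, 4], [2, 3, 4], [3, 1, 4]],
                       ["s1", "s2", "s3"], ["g1", "gx", "g2"])
        rho = h.per_taxon_spearman(a, b)
        assert rho["g1"] == pytest.approx(1.0)
        assert rho["g2"] == 0.0

    def test_spearman_matches_rank_then_pearson(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(30), rng.random(30)
        from scipy.stats import spearmanr

        assert _corr(x, y, "spearman") == pytest.approx(spearmanr(x, y)[0])

    def _calls(self):
        lin_a = parse_lineage("k__Bacteria;p__P;c__C;o__O;f__F;g__G1")
        lin_b = parse_lineage("k__Bacteria;p__P;c__C;o__O;f__F;g__G2")
        full = dict.fromkeys(RANKS, 1.0)
        partial = dict.fromkeys(RANKS, 1.0)
        partial["genus"] = 0.3
        return {
            "o1": h.TaxonomyCall(lin_a, full, "genus"),
            "o2": h.TaxonomyCall(lin_a, full, "genus"),
            "o3": h.TaxonomyCall(lin_b, partial, "family"),
        }

    def test_collapse_sums_and_bins_unclassified(self):
        t = table_from([[3, 4, 2]], ["s1"], ["o1", "o2", "o3"])
        g = h.collapse_to_genus(t, self._calls())
        assert g.counts.loc["s1", "g__G1"] == 7
        assert g.counts.loc["s1", "unclassified_f__F"] == 2
        assert g.grand_total() == t.grand_total()
        assert h.unclassified_fraction(g) == pytest.approx(2 / 9)
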