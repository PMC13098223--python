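import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform

from votuforge.ecology import (
    accumulation_curve,
    bray_curtis,
    core_virome,
    host_group_abundance,
    kruskal_wallis,
    nb_richness_model,
    pcoa,
    permanova,
    prevalence,
    rank_tests,
    richness,
    wilcoxon_rank_sum,
)

from conftest import SEED


def _frame(rows, index=None, cols=None):
    arr = np.asarray(rows, dtype=float)
    index = index or [f"s{i}" for i in range(arr.shape[0])]
    cols = cols or [f"v{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=index, columns=cols)


class TestRichnessAndCore:
    def test_richness_counts_nonzero(self):
        df = _frame([[0, 0, 0], [0.1, 0, 0.2], [0.1, 0.1, 0.1]])
        assert richness(df).tolist() == [0, 2, 3]

    def test_core_virome_thresholds(self):
        df = _frame(np.vstack([np.ones((10, 1)), np.zeros((0, 1))]))
        meta = pd.DataFrame({"region": ["ileum"] * 10}, index=df.index)
        core = core_virome(df, meta)
        assert (core["n_core"] == 1).all()  # present everywhere: all thresholds

    def test_rare_votu_below_all_thresholds(self):
        col = np.zeros((10, 1))
        col[0] = 1.0
        meta = pd.DataFrame({"region": ["caeca"] * 10}, index=[f"s{i}" for i in range(10)])
        core = core_virome(_frame(col), meta)
        assert (core["n_core"] == 0).all()

    def test_prevalence_within_region_only(self):
        df = _frame([[1], [1], [0], [0]])
        groups = pd.Series(["a", "a", "b", "b"], index=df.index)
        prev = prevalence(df, groups)
        assert prev.set_index("group")["prevalence"].to_dict() == {"a": 1.0, "b": 0.0}


class TestAccumulation:
    def test_identical_samples_flat_after_first(self):
        df = _frame([[1, 1, 0]] * 5)
        curve = accumulation_curve(df, n_perm=20, seed=SEED)
        assert np.allclose(curve.mean, 2.0)

    def test_disjoint_samples_exact_closed_form(self):
        df = _frame(np.kron(np.eye(4), np.ones((1, 5))))
        curve = accumulation_curve(df, n_perm=50, seed=SEED)
        assert np.array_equal(curve.mean, [5.0, 10.0, 15.0, 20.0])
        assert np.allclose(curve.sd, 0.0)

    def test_final_value_is_total_distinct(self, rng):
        df = _frame(rng.random((8, 30)) * (rng.random((8, 30)) > 0.6))
        for seed in range(3):
            curve = accumulation_curve(df, n_perm=10, seed=seed)
            assert curve.mean[-1] == (df > 0).any(axis=0).sum()


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        df = _frame([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        d = bray_curtis(df)
        assert d.iloc[0, 1] == 0.0 and d.iloc[0, 2] == 1.0

    def test_matches_scipy_oracle(self, rng):
        df = _frame(rng.random((15, 40)))
        mine = bray_curtis(df).values
        oracle = squareform(pdist(df.values, metric="braycurtis"))
        assert np.abs(mine - oracle).max() < 1e-12


class TestPermanova:
    def test_maximal_separation_minimum_p(self, rng):
        # two groups with disjoint vOTU support: F is never exceeded
        a = np.hstack([rng.random((10, 8)), np.zeros((10, 8))])
        b = np.hstack([np.zeros((10, 8)), rng.random((10, 8))])
        d = bray_curtis(_frame(np.vstack([a, b])))
        res = permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=SEED)
        assert res.p == pytest.approx(1.0 / (1 + 999))
        assert res.R2 > 0.5

    def test_matches_library_oracle(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        df = _frame(rng.random((18, 10)))
        d = bray_curtis(df)
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        mine = permanova(d, labels, n_perm=99, seed=SEED)
        ref = sk_permanova(DistanceMatrix(d.values, ids=list(d.index)), grouping=labels,
                           permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)
        k, n = 3, 18
        r2_ref = ref["test statistic"] * (k - 1) / (ref["test statistic"] * (k - 1) + (n - k))
        assert mine.R2 == pytest.approx(r2_ref, abs=1e-10)

    def test_label_permutation_invariance(self, rng):
        df = _frame(rng.random((12, 6)))
        d = bray_curtis(df)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = permanova(d, labels, n_perm=199, seed=SEED)
        perm = rng.permutation(12)
        res2 = permanova(d.values[np.ix_(perm, perm)], labels[perm], n_perm=199, seed=SEED)
        assert res2.pseudo_F == pytest.approx(res.pseudo_F)
        assert res2.R2 == pytest.approx(res.R2)

    def test_singleton_group_rejected(self, rng):
        d = bray_curtis(_frame(rng.random((5, 4))))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a", "a", "b"], n_perm=9)


class TestPcoa:
    def test_equilateral_triangle_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        _, evals = pcoa(d)
        assert evals[0] == pytest.approx(evals[1])
        assert evals[0] > 0

    def test_planted_geometry_recovered(self, rng):
        pts = rng.random((12, 2))
        d = cdist(pts, pts)
        coords, evals = pcoa(d)
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts, coords.values[:, :2])
        assert disparity < 1e-8
        assert (evals[2:] < 1e-8).all()  # only two real axes

    def test_duplicate_sample_identical_coordinates(self, rng):
        pts = rng.random((6, 3))
        pts[5] = pts[0]
        d = cdist(pts, pts)
        coords, _ = pcoa(d)
        assert np.allclose(coords.values[0], coords.values[5], atol=1e-9)


class TestRankTests:
    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res["p"] == 1.0

    def test_separated_groups_match_exact_oracle(self):
        mine = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        ref = stats.mannwhitneyu([1, 2, 3], [10, 11, 12], alternative="two-sided",
                                 method="exact")
        assert mine["p"] == pytest.approx(ref.pvalue, abs=1e-12)
        assert mine["method"] == "exact"

    def test_tie_heavy_matches_asymptotic_oracle(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(1, 5, 33).astype(float)
        mine = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        assert mine["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_branch_matches_oracle(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=8) + 0.5
        mine = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert mine["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_kruskal_matches_oracle_with_ties(self, rng):
        v = rng.integers(0, 5, 45).astype(float)
        g = rng.choice(list("abc"), 45)
        mine = kruskal_wallis(v, g)
        ref = stats.kruskal(*[v[g == k] for k in "abc"])
        assert mine["H"] == pytest.approx(ref.statistic, abs=1e-10)
        assert mine["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_pairwise_matrix_with_holm(self, rng):
        v = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10), rng.normal(6, 1, 10)])
        g = np.repeat(list("abc"), 10)
        res = rank_tests(v, g)
        assert len(res["pairwise"]) == 3
        assert (res["pairwise"]["p_holm"] >= res["pairwise"]["p"] - 1e-15).all()


class TestHostGroupAbundance:
    def test_unassigned_pool_to_no_host(self):
        df = _frame([[0.1, 0.2], [0.3, 0.1]])
        hosts = pd.DataFrame({"family": []}, index=pd.Index([], name="votu"), dtype=object)
        out = host_group_abundance(df, hosts)
        assert list(out.columns) == ["no_host"]
        assert np.allclose(out["no_host"].values, df.sum(axis=1).values)

    def test_family_sums(self):
        df = _frame([[0.1, 0.2, 0.05]])
        hosts = pd.DataFrame({"family": ["Lactobacillaceae", "Lactobacillaceae", np.nan]},
                             index=["v0", "v1", "v2"])
        out = host_group_abundance(df, hosts)
        assert out.loc["s0", "Lactobacillaceae"] == pytest.approx(0.3)
        assert out.loc["s0", "no_host"] == pytest.approx(0.05)

    def test_totals_conserved(self, rng):
        df = _frame(rng.random((6, 10)))
        hosts = pd.DataFrame({"genus": rng.choice(["Lactobacillus", "Bacteroides", None], 10)},
                             index=df.columns)
        out = host_group_abundance(df, hosts, rank="genus")
        assert np.allclose(out.sum(axis=1), df.sum(axis=1))


class TestNbRichnessModel:
    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            nb_richness_model([1.5, 2.0], ["a", "b"], ["x", "y"])

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            nb_richness_model([1, 2, 3, 4], ["a"] * 4, ["x", "y", "x", "y"])

    def test_planted_breed_effect_detected(self, rng):
        breed = np.repeat(["LB", "LSL"], 40)
        diet = np.tile(["c", "p"], 40)
        mu = 40.0 * np.where(breed == "LSL", 2.0, 1.0)
        size = 1 / 0.2
        counts = rng.negative_binomial(n=size, p=size / (size + mu))
        res = nb_richness_model(counts, breed, diet)
        assert res["family"] == "negative_binomial"
        assert res["coefficients"].loc["breed[T.LSL]", "p"] < 0.01
        assert 0.05 < res["alpha"] < 0.6

    def test_null_interaction_calibrated(self):
        # interaction p approximately uniform when diet has no effect
        rng = np.random.default_rng(SEED)
        pvals = []
        for _ in range(60):
            breed = np.repeat(["LB", "LSL"], 30)
            diet = np.tile(["c", "p"], 30)
            mu = 40.0 * np.where(breed == "LSL", 1.5, 1.0)
            size = 1 / 0.3
            counts = rng.negative_binomial(n=size, p=size / (size + mu))
            res = nb_richness_model(counts, breed, diet)
            pvals.append(res["coefficients"].loc["breed[T.LSL]:diet[T.p]", "p"])
        assert 0.2 < np.mean(pvals) < 0.8
        assert np.mean(np.array(pvals) < 0.05) <= 0.15
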