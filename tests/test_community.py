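import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd
import scipy.stats
from skbio import DistanceMatrix

from limnotraj.io import AsvCountTable, rarefy
from limnotraj.community import (
    bray_curtis,
    env_pca,
    pcoa,
    permanova,
    richness,
    shannon,
    spearman,
)


def table_from(array, prefix="s"):
    arr = np.asarray(array)
    df = pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"a{j}" for j in range(arr.shape[1])],
    )
    return AsvCountTable(df)


class TestAlphaDiversity:
    def test_richness_counts_positive_entries(self):
        assert richness([5, 0, 1]) == 2
        assert richness([0, 0, 0]) == 0

    def test_rarefied_richness_never_exceeds_original(self, rng):
        counts = rng.integers(0, 20, size=(5, 60))
        counts[:, 0] += 200
        table = table_from(counts)
        rare = rarefy(table, depth=150, seed=1)
        for sid in rare.sample_ids:
            assert richness(rare.counts.loc[sid]) <= richness(table.counts.loc[sid])

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10, 10, 10, 10], math.log(4)),
            ([42], 0.0),
            ([75, 25], 0.56234),  # direct evaluation of -sum p ln p
        ],
    )
    def test_shannon_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-4)

    def test_shannon_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_shannon_scale_invariant(self, rng):
        counts = rng.integers(0, 50, size=30) + 1
        assert shannon(counts * 7) == pytest.approx(shannon(counts), rel=1e-12)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = bray_curtis(table_from([[3, 1, 2], [3, 1, 2]]))
        assert dm[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        dm = bray_curtis(table_from([[1, 0], [0, 1]]))
        assert dm[0, 1] == 1.0

    def test_formula_example(self):
        dm = bray_curtis(table_from([[6, 2, 0], [2, 2, 4]]))
        assert dm[0, 1] == pytest.approx(0.5)  # 8/16

    def test_matches_brute_force_formula(self, rng):
        """pdist-backed result equals the explicit |x-y| / (x+y) sum on
        random tables (independent formula oracle)."""
        counts = rng.integers(0, 30, size=(8, 15)) + 1
        table = table_from(counts)
        dm = bray_curtis(table)
        for j, k in itertools.combinations(range(8), 2):
            x, y = counts[j].astype(float), counts[k].astype(float)
            expected = np.abs(x - y).sum() / (x + y).sum()
            assert dm[j, k] == pytest.approx(expected, abs=1e-12)

    def test_range_symmetry_diagonal(self, rng):
        counts = rng.integers(0, 9, size=(10, 12)) + 1
        dm = bray_curtis(table_from(counts))
        data = dm.data
        assert np.allclose(data, data.T)
        assert np.all(np.diag(data) == 0)
        assert data.min() >= 0 and data.max() <= 1


class TestPcoa:
    def test_two_samples(self):
        dm = DistanceMatrix([[0, 0.8], [0.8, 0]], ids=["a", "b"])
        ordn = pcoa(dm)
        coords = ordn.coordinates.to_numpy().ravel()
        assert sorted(np.round(coords, 10)) == [-0.4, 0.4]
        assert ordn.variance_fraction[0] == pytest.approx(1.0)

    def test_three_equidistant_points(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        ordn = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert ordn.eigenvalues.size == 2
        assert ordn.variance_fraction == pytest.approx([0.5, 0.5])

    def test_euclidean_embedding_reconstructs_distances(self, rng):
        """Metric-embedding oracle: PCoA of Euclidean distances of planar
        points reproduces all pairwise distances within 1e-8."""
        pts = rng.normal(size=(12, 2))
        d = ssd.squareform(ssd.pdist(pts))
        ordn = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(12)]))
        rec = ssd.squareform(ssd.pdist(ordn.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_agrees_with_skbio_reference(self, rng):
        import skbio.stats.ordination

        counts = rng.integers(0, 20, size=(9, 25)) + 1
        dm = bray_curtis(table_from(counts))
        ours = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(dm, method="eigh")
        k = ours.eigenvalues.size
        assert np.allclose(ours.eigenvalues, ref.eigvals.to_numpy()[:k], atol=1e-8)
        # coordinates agree up to per-axis sign
        for ax in range(min(3, k)):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = ref.samples.iloc[:, ax].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(Exception):
            pcoa(DistanceMatrix(np.array([[0, 1], [0.5, 0]]), ids=["a", "b"]))


def brute_force_one_way_F(d, labels):
    """Independent PERMANOVA pseudo-F from within/between squared distances."""
    n = len(labels)
    sst = (d**2)[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        sub = d[np.ix_(idx, idx)]
        ssw += (sub**2)[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(set(labels))
    return ((sst - ssw) / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def test_fully_separated_groups_r2_one(self):
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        dm = DistanceMatrix(d, ids=list("abcd"))
        fac = pd.DataFrame({"g": ["x", "x", "y", "y"]}, index=list("abcd"))
        res = permanova(dm, fac, terms=("g",), n_perm=99, seed=0)
        assert res.table.loc["g", "R2"] == pytest.approx(1.0, abs=1e-9)

    def test_exhaustive_enumeration_matches_brute_force(self, rng):
        """Single-factor p at n=6 equals an exhaustive-permutation oracle
        built from the within/between distance decomposition."""
        pts = rng.normal(size=(6, 3))
        d = ssd.squareform(ssd.pdist(pts))
        labels = ["a", "a", "a", "b", "b", "b"]
        perms = np.array(list(itertools.permutations(range(6))))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        fac = pd.DataFrame({"g": labels}, index=[str(i) for i in range(6)])
        res = permanova(dm, fac, terms=("g",), permutations=perms)
        f_obs = brute_force_one_way_F(d, labels)
        f_perm = np.array(
            [brute_force_one_way_F(d[np.ix_(p, p)], labels) for p in perms]
        )
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(f_obs, rel=1e-9)
        assert res.table.loc["g", "p_value"] == pytest.approx(
            np.mean(f_perm >= f_obs - 1e-12), abs=1e-12
        )

    def test_r2_partition_sums_to_one(self, rng, metadata_grid):
        meta = metadata_grid(["A", "B", "C"], n_months=6)
        counts = rng.integers(0, 25, size=(len(meta), 20)) + 1
        df = pd.DataFrame(
            counts, index=meta.index, columns=[f"a{j}" for j in range(20)]
        )
        dm = bray_curtis(AsvCountTable(df))
        res = permanova(dm, meta, n_perm=99, seed=5)
        terms_plus_resid = res.table.loc[
            ["lake", "season", "lake:season", "residual"], "R2"
        ].sum()
        assert terms_plus_resid == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_identical_p(self, rng, metadata_grid):
        meta = metadata_grid(["A", "B"], n_months=4)
        counts = rng.integers(0, 25, size=(len(meta), 15)) + 1
        dm = bray_curtis(
            AsvCountTable(
                pd.DataFrame(
                    counts, index=meta.index, columns=[f"a{j}" for j in range(15)]
                )
            )
        )
        r1 = permanova(dm, meta, terms=("lake", "season"), n_perm=199, seed=7)
        r2 = permanova(dm, meta, terms=("lake", "season"), n_perm=199, seed=7)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_agrees_with_skbio_one_way(self, rng):
        """Cross-check the sequential machinery against scikit-bio's one-way
        PERMANOVA on the same distances and grouping."""
        import skbio.stats.distance

        counts = rng.integers(0, 25, size=(12, 18)) + 1
        dm = bray_curtis(table_from(counts))
        labels = ["x"] * 6 + ["y"] * 6
        fac = pd.DataFrame({"g": labels}, index=list(dm.ids))
        ours = permanova(dm, fac, terms=("g",), n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            dm, grouping=np.array(labels), permutations=99
        )
        assert ours.table.loc["g", "pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-9
        )

    def test_zero_residual_df_reported_na(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        dm = DistanceMatrix(d, ids=["a", "b"])
        fac = pd.DataFrame({"g": ["x", "y"]}, index=["a", "b"])
        res = permanova(dm, fac, terms=("g",), n_perm=9, seed=0)
        assert np.isnan(res.table.loc["g", "pseudo_F"])
        assert np.isnan(res.table.loc["g", "p_value"])


class TestSpearman:
    def test_strictly_monotone(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.rho == pytest.approx(1.0)
        res = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson_oracle(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        res = spearman(x, y)
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_large_n_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = spearman(x, y)
        ref = scipy.stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_p_small_n_is_permutation_fraction(self):
        x, y = [1, 2, 3, 4], [1, 2, 4, 3]
        res = spearman(x, y)
        # brute force over all 24 permutations of y
        rx = scipy.stats.rankdata(x)
        obs = abs(np.corrcoef(rx, scipy.stats.rankdata(y))[0, 1])
        hits = sum(
            abs(np.corrcoef(rx, scipy.stats.rankdata(np.array(y)[list(p)]))[0, 1])
            >= obs - 1e-12
            for p in itertools.permutations(range(4))
        )
        assert res.p_value == pytest.approx(hits / 24)

    def test_constant_input_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.degenerate and np.isnan(res.rho)


class TestEnvPca:
    def test_perfectly_correlated_pair(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = pd.DataFrame({"u": x, "v": 3 * x + 1})
        res = env_pca(df)
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert np.allclose(res.cos2.iloc[:, 0], 1.0)

    def test_cos2_rows_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        res = env_pca(df)
        assert np.allclose(res.cos2.sum(axis=1), 1.0, atol=1e-9)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            env_pca(df)

    def test_orthogonal_equal_variance_gives_equal_eigenvalues(self):
        df = pd.DataFrame({"u": [1.0, -1.0, 1.0, -1.0], "v": [1.0, 1.0, -1.0, -1.0]})
        res = env_pca(df)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
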