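import itertools

import numpy as np
import pandas as pd
import pytest

from musselpipe import differentiation as diff
from musselpipe.datamodel import DataError, GenotypeMatrix

from .conftest import make_two_pop_gm
from .oracles import newick_tip_distances, random_additive_matrix, wc_anova_oracle

AA, Aa, aa = (0, 0), (0, 1), (1, 1)


class TestWcFst:
    def test_fixed_difference_theta_one(self):
        gm = make_two_pop_gm([AA] * 10, [aa] * 10)
        assert diff.wc_fst(gm, locus="L1") == pytest.approx(1.0)

    def test_identical_populations_theta_near_zero(self):
        rng = np.random.default_rng(0)
        genos = lambda: [tuple(sorted(rng.binomial(1, 0.5, 2))) for _ in range(400)]
        gm = make_two_pop_gm(genos(), genos())
        assert abs(diff.wc_fst(gm, locus="L1")) < 0.02

    def test_two_pop_toy_matches_anova_oracle(self):
        rng = np.random.default_rng(1)
        g1 = [tuple(sorted(rng.binomial(1, 0.2, 2))) for _ in range(10)]
        g2 = [tuple(sorted(rng.binomial(1, 0.8, 2))) for _ in range(10)]
        gm = make_two_pop_gm(g1, g2)
        want = wc_anova_oracle([g1, g2])
        assert diff.wc_fst(gm, locus="L1") == pytest.approx(want, abs=1e-12)

    def test_matches_anova_oracle_exhaustively(self):
        """Theta equals the nested-ANOVA oracle on every 2-population,
        1-locus genotype configuration with up to 3 individuals per side."""
        configs = []
        for n in (2, 3):
            for c in itertools.combinations_with_replacement([AA, Aa, aa], n):
                configs.append(list(c))
        checked = 0
        for g1 in configs:
            for g2 in configs:
                gm = make_two_pop_gm(g1, g2)
                got = diff.wc_fst(gm, locus="L1")
                want = wc_anova_oracle([g1, g2])
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-10), (g1, g2)
                checked += 1
        assert checked == 256

    def test_multilocus_is_ratio_of_sums(self, default_study):
        gm = default_study["gm"]
        per_locus, multi = diff.wc_fst(gm)
        assert np.isfinite(multi)
        assert -0.05 < multi <= 1.0
        # per-locus values on the taxon-wide scale span a broad range
        vals = per_locus.dropna()
        assert vals.max() > 0.5
        assert vals.min() < 0.15

    def test_within_taxon_fst_much_smaller_than_between(self, default_study):
        gm = default_study["gm"]
        _, between = diff.wc_fst(gm, ["TR1", "ED1"])
        _, within = diff.wc_fst(gm, ["ED1", "INB"])
        assert between > 0.5
        assert within < 0.1
        assert within < between / 5


class TestFstPermutation:
    def test_fixed_difference_minimal_p(self):
        gm = make_two_pop_gm([AA] * 8, [aa] * 8)
        theta, p = diff.fst_permutation_test(gm, "P1", "P2", n_perm=99, seed=0)
        assert theta == pytest.approx(1.0)
        assert p <= 2 / 100

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        g = lambda: [tuple(sorted(rng.binomial(1, 0.5, 2))) for _ in range(8)]
        gm = make_two_pop_gm(g(), g())
        a = diff.fst_permutation_test(gm, "P1", "P2", n_perm=50, seed=11)
        b = diff.fst_permutation_test(gm, "P1", "P2", n_perm=50, seed=11)
        assert a == b

    def test_singleton_population_rejected(self):
        gm = make_two_pop_gm([AA], [aa, aa])
        with pytest.raises(DataError):
            diff.fst_permutation_test(gm, "P1", "P2", n_perm=10, seed=0)


class TestOutlierScan:
    def test_extreme_locus_flagged(self):
        rng = np.random.default_rng(0)
        n, L = 30, 40
        loci = [f"L{j}" for j in range(L)]
        geno = np.empty((2 * n, L, 2), dtype=np.int8)
        for j in range(L - 1):
            p1, p2 = rng.beta(8, 8, 2) * 0.4 + 0.3, rng.beta(8, 8, 2) * 0.4 + 0.3
            geno[:n, j] = np.sort(rng.binomial(1, p1[0], (n, 2)), axis=1)
            geno[n:, j] = np.sort(rng.binomial(1, p2[0], (n, 2)), axis=1)
        geno[:n, L - 1] = 0
        geno[n:, L - 1] = 1
        gm = GenotypeMatrix(
            [f"P{1 + (i >= n)}_{i}" for i in range(2 * n)],
            ["P1"] * n + ["P2"] * n,
            loci,
            {l: ("A", "C") for l in loci},
            geno,
        )
        scan = diff.fst_outlier_scan(gm, n_sim=3000, seed=0)
        assert not scan.skipped
        assert f"L{L-1}" in scan.outliers

    def test_simulation_floor_enforced(self, default_study):
        with pytest.raises(DataError):
            diff.fst_outlier_scan(default_study["gm"], n_sim=10, seed=0)

    def test_envelope_ordering(self, default_study):
        scan = diff.fst_outlier_scan(default_study["gm"], n_sim=2000, seed=0)
        t = scan.table.dropna()
        assert (t["lower"] <= t["upper"]).all()


class TestLd:
    def test_pair_count(self):
        assert diff.n_ld_pairs(66) == 2145

    def test_duplicate_locus_minimal_p(self):
        rng = np.random.default_rng(0)
        genos = np.sort(rng.binomial(1, 0.5, (40, 2)), axis=1).astype(np.int8)
        geno = np.stack([genos, genos], axis=1)
        gm = GenotypeMatrix(
            [f"P1_{i}" for i in range(40)], ["P1"] * 40, ["LA", "LB"],
            {"LA": ("A", "C"), "LB": ("A", "C")}, geno,
        )
        p = diff.ld_pair_test(gm, "P1", "LA", "LB", n_perm=199, seed=0)
        assert p <= 2 / 200

    def test_zero_variance_table_p_one(self):
        geno = np.zeros((10, 2, 2), dtype=np.int8)
        geno[:, 1, :] = np.sort(
            np.random.default_rng(0).binomial(1, 0.5, (10, 2)), axis=1
        )
        gm = GenotypeMatrix(
            [f"P1_{i}" for i in range(10)], ["P1"] * 10, ["LA", "LB"],
            {"LA": ("A", "C"), "LB": ("A", "C")}, geno,
        )
        assert diff.ld_pair_test(gm, "P1", "LA", "LB", n_perm=50, seed=0) == 1.0


class TestNjTree:
    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        """NJ reproduces the generating tree's tip distances for additive
        matrices (random binary trees, random branch lengths)."""
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            labels, D = random_additive_matrix(n_taxa, rng)
            newick = diff.nj_tree(pd.DataFrame(D, index=labels, columns=labels))
            got = newick_tip_distances(newick, labels)
            np.testing.assert_allclose(got, D, atol=1e-8)

    def test_three_taxa_closed_form(self):
        # three-point formulas: d(A,x)=(ab+ac-bc)/2 etc.
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        newick = diff.nj_tree(D)
        got = newick_tip_distances(newick, list("ABC"))
        np.testing.assert_allclose(got, D.to_numpy(), atol=1e-8)

    def test_two_cluster_bipartition_preserved(self):
        labels = list("ABCD")
        D = pd.DataFrame(
            [[0, 0.1, 1, 1], [0.1, 0, 1, 1], [1, 1, 0, 0.1], [1, 1, 0.1, 0]],
            index=labels, columns=labels,
        )
        newick = diff.nj_tree(D)
        got = newick_tip_distances(newick, labels)
        assert got[0, 1] < got[0, 2] and got[2, 3] < got[1, 2]

    def test_fewer_than_three_taxa_rejected(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(DataError):
            diff.nj_tree(D)

    def test_three_taxon_clades_on_default_scenario(self, default_study):
        gm = default_study["gm"].subset_pops(["TR1", "SW1", "ED1", "INB", "GA1"])
        m = diff.pairwise_fst(gm, n_perm=20, seed=0)
        newick = diff.nj_tree(m.distance_matrix())
        labels = ["TR1", "SW1", "ED1", "INB", "GA1"]
        got = newick_tip_distances(newick, labels)
        d = pd.DataFrame(got, index=labels, columns=labels)
        # trossulus-side pair and edulis pair each closer than cross-taxon
        assert d.loc["TR1", "SW1"] < d.loc["TR1", "ED1"]
        assert d.loc["ED1", "INB"] < d.loc["ED1", "TR1"]
        assert d.loc["ED1", "INB"] < d.loc["ED1", "GA1"]


class TestCorrespondenceAnalysis:
    def _cluster_table(self):
        rng = np.random.default_rng(0)
        rows = {}
        centers = {"c1": 0.1, "c2": 0.5, "c3": 0.9}
        for c, p in centers.items():
            for k in range(2):
                counts = rng.binomial(60, p, size=6)
                row = np.empty(12)
                row[0::2] = counts
                row[1::2] = 60 - counts
                rows[f"{c}_{k}"] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_inertia_sums_to_100(self):
        res = diff.correspondence_analysis(self._cluster_table())
        assert res.inertia_pct.sum() == pytest.approx(100.0)

    def test_identical_rows_identical_coordinates(self):
        t = self._cluster_table()
        t.loc["c1_1"] = t.loc["c1_0"]
        res = diff.correspondence_analysis(t)
        np.testing.assert_allclose(
            res.row_coords.loc["c1_0"], res.row_coords.loc["c1_1"], atol=1e-10
        )

    def test_axis1_separates_extreme_clusters_and_matches_eigen_oracle(self):
        t = self._cluster_table()
        res = diff.correspondence_analysis(t)
        ax1 = res.row_coords["axis1"]
        c1 = ax1[["c1_0", "c1_1"]].mean()
        c2 = ax1[["c2_0", "c2_1"]].mean()
        c3 = ax1[["c3_0", "c3_1"]].mean()
        assert abs(c1 - c3) > abs(c1 - c2)
        assert abs(c1 - c3) > abs(c2 - c3)
        # independent eigendecomposition of the standardized matrix
        N = t.to_numpy(dtype=float)
        P = N / N.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        eigvals = np.sort(np.linalg.eigvalsh(S @ S.T))[::-1]
        eigvals = eigvals[eigvals > 1e-12]
        want = 100 * eigvals / eigvals.sum()
        np.testing.assert_allclose(res.inertia_pct[: len(want)], want, atol=1e-8)

    def test_rank0_rejected(self):
        with pytest.raises(DataError):
            diff.correspondence_analysis(pd.DataFrame(np.zeros((3, 4))))
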