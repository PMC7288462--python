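import numpy as np
import pytest

from musselpipe import hybrids as hyb
from musselpipe import synthdata as sd
from musselpipe.datamodel import DataError, GenotypeMatrix

from .conftest import STUDY_SEED


def panel_gm(n_loci=16, hom="char"):
    """One individual homozygous at every panel locus (char or alt allele)."""
    loci = [f"L{j}" for j in range(n_loci)]
    code = 0 if hom == "char" else 1
    geno = np.full((1, n_loci, 2), code, dtype=np.int8)
    gm = GenotypeMatrix(
        ["X_1"], ["X"], loci, {l: ("A", "C") for l in loci}, geno
    )
    panel = hyb.DiagnosticPanel(
        "trossulus", loci, {l: "A" for l in loci}, {l: 0.95 for l in loci}
    )
    return gm, panel


class TestPanelSelection:
    def test_default_study_panel_is_sixteen(self, default_study):
        panel = hyb.select_diagnostic_panel(
            default_study["gm"], default_study["refs"], "trossulus"
        )
        assert len(panel) == 16
        assert set(panel.loci) == set(
            default_study["profiles"][0].diagnostic_loci
        )

    def test_impossible_threshold_on_non_fixed_data_errors(self):
        rng = np.random.default_rng(0)
        n = 100
        def pure(p):
            return np.sort(rng.binomial(1, 1 - p, (n, 1, 2)), axis=2).astype(np.int8)
        geno = np.concatenate([pure(0.9), pure(0.1), pure(0.1)])
        gm = GenotypeMatrix(
            [f"{p}_{i}" for p in ("T", "E", "G") for i in range(n)],
            ["T"] * n + ["E"] * n + ["G"] * n,
            ["L1"], {"L1": ("A", "C")}, geno,
        )
        refs = {"tross": ["T"], "edu": ["E"], "gallo": ["G"]}
        with pytest.raises(DataError, match="relax"):
            hyb.select_diagnostic_panel(gm, refs, "tross", d_high=1.0, d_low=0.0)

    def test_threshold_boundary(self):
        # 0.95/0.05/0.05 qualifies; 0.95/0.5/0.05 does not
        rng = np.random.default_rng(0)
        n = 200
        def pure(p, pop):
            g = np.sort(rng.binomial(1, 1 - p, (n, 1, 2)), axis=2).astype(np.int8)
            return g
        geno = np.concatenate([pure(0.95, "T"), pure(0.05, "E"), pure(0.05, "G")])
        gm = GenotypeMatrix(
            [f"{p}_{i}" for p in ("T", "E", "G") for i in range(n)],
            ["T"] * n + ["E"] * n + ["G"] * n,
            ["L1"], {"L1": ("A", "C")}, geno,
        )
        refs = {"tross": ["T"], "edu": ["E"], "gallo": ["G"]}
        panel = hyb.select_diagnostic_panel(gm, refs, "tross", d_high=0.9, d_low=0.2)
        assert panel.loci == ["L1"]
        geno2 = np.concatenate([pure(0.95, "T"), pure(0.5, "E"), pure(0.05, "G")])
        gm2 = GenotypeMatrix(gm.individuals, gm.populations, ["L1"], gm.alleles, geno2)
        with pytest.raises(DataError):
            hyb.select_diagnostic_panel(gm2, refs, "tross", d_high=0.9, d_low=0.2)


class TestHybridIndex:
    def test_homozygous_characteristic_scores_one(self):
        gm, panel = panel_gm(hom="char")
        assert hyb.hybrid_index(gm, panel).per_individual["hi"].iloc[0] == 1.0

    def test_homozygous_alternative_scores_zero(self):
        gm, panel = panel_gm(hom="alt")
        assert hyb.hybrid_index(gm, panel).per_individual["hi"].iloc[0] == 0.0

    def test_heterozygous_scores_half(self):
        gm, panel = panel_gm()
        gm.geno[0, :, 1] = 1
        assert hyb.hybrid_index(gm, panel).per_individual["hi"].iloc[0] == 0.5

    def test_missing_loci_shrink_denominator(self):
        gm, panel = panel_gm()
        gm.geno[0, :8, :] = -1
        res = hyb.hybrid_index(gm, panel)
        assert res.per_individual["n_loci"].iloc[0] == 8
        assert res.per_individual["hi"].iloc[0] == 1.0

    def test_empty_panel_rejected(self):
        gm, panel = panel_gm()
        panel.loci = []
        with pytest.raises(DataError):
            hyb.hybrid_index(gm, panel)

    def test_simulated_f1_population_mean_half_variance_tiny(self):
        profiles = sd.make_taxon_profiles(
            n_loci=16, n_diagnostic={"trossulus": 16}, d_high=1.0, d_low=0.0,
            seed=0,
        )
        prof = {p.taxon: p for p in profiles}
        rng = np.random.default_rng(0)
        rows = [
            sd.sample_individual(("F1", "trossulus", "edulis"), prof, rng=rng)
            for _ in range(30)
        ]
        gm = GenotypeMatrix(
            [f"P1_{i}" for i in range(30)], ["P1"] * 30, profiles[0].loci,
            profiles[0].alleles, np.stack(rows),
        )
        panel = hyb.DiagnosticPanel(
            "trossulus", profiles[0].diagnostic_loci,
            profiles[0].characteristic_allele,
            {l: 1.0 for l in profiles[0].diagnostic_loci},
        )
        res = hyb.hybrid_index(gm, panel)
        assert res.per_population.loc["P1", "mean_hi"] == pytest.approx(0.5)
        assert res.per_population.loc["P1", "v_hi"] == pytest.approx(0.0, abs=1e-12)


class TestClassGenotypeFrequency:
    def test_f1_fixed_parents_all_het(self):
        assert hyb.class_genotype_frequency("F1", 1.0, 0.0, (0, 1)) == 1.0

    def test_f2_fixed_parents_quarter_half_quarter(self):
        probs = hyb.class_genotype_frequency("F2", 1.0, 0.0)
        assert probs[0, 0] == pytest.approx(0.25)
        assert probs[0, 1] == pytest.approx(0.5)
        assert probs[1, 1] == pytest.approx(0.25)

    def test_backcross_gamete_algebra(self):
        probs = hyb.class_genotype_frequency("BC_A", 1.0, 0.0)
        assert probs[0, 0] == pytest.approx(0.5)
        assert probs[0, 1] == pytest.approx(0.5)
        assert probs[1, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize("cls", hyb.HYBRID_CLASSES)
    def test_sums_to_one_over_grid(self, cls):
        for pa in np.linspace(0, 1, 6):
            for pb in np.linspace(0, 1, 6):
                probs = hyb.class_genotype_frequency(cls, pa, pb)
                assert probs.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("cls", hyb.HYBRID_CLASSES)
    def test_sums_to_one_triallelic(self, cls):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pa, pb = rng.dirichlet([1, 1, 1]), rng.dirichlet([1, 1, 1])
            assert hyb.class_genotype_frequency(cls, pa, pb).sum() == pytest.approx(1.0)


class TestAssignHybridClasses:
    def test_fully_heterozygous_posterior_closed_form(self):
        """With fixed parental frequencies, a fully heterozygous individual
        at L loci has posterior P(F1) = 1 / (1 + 3 * 0.5^L): classes F2 and
        both backcrosses each give the het probability 0.5 per locus."""
        L = 16
        lik = {
            c: hyb.class_genotype_frequency(c, 1.0, 0.0, (0, 1)) ** 1
            for c in hyb.HYBRID_CLASSES
        }
        post_f1 = np.prod([hyb.class_genotype_frequency("F1", 1.0, 0.0, (0, 1))] * L)
        others = sum(
            np.prod([hyb.class_genotype_frequency(c, 1.0, 0.0, (0, 1))] * L)
            for c in ("F2", "BC_A", "BC_B")
        )
        assert lik["pure_A"] == 0.0
        assert post_f1 / (post_f1 + others) == pytest.approx(1 / (1 + 3 * 0.5**16))

    def test_reference_individual_assigned_pure(self, fixed_panel_study):
        gm = fixed_panel_study["gm"]
        refs = fixed_panel_study["refs"]
        panel_loci = fixed_panel_study["profiles"][0].diagnostic_loci
        post = hyb.assign_hybrid_classes(
            gm, refs["trossulus"], refs["edulis"], loci=panel_loci
        )
        for ind in gm.individuals[:5]:  # TR1 reference individuals
            assert post.map_class[ind] == "pure_A"
            assert post.map_probability[ind] > 0.99

    def test_zero_loci_returns_prior(self, default_study):
        gm = default_study["gm"]
        refs = default_study["refs"]
        post = hyb.assign_hybrid_classes(gm, refs["trossulus"], refs["edulis"], loci=[])
        np.testing.assert_allclose(post.posterior.iloc[0], [1 / 6] * 6)


class TestSupervisedAncestry:
    def _fixed_cluster_gm(self, genotype_code):
        loci = [f"L{j}" for j in range(10)]
        geno = np.full((1, 10, 2), genotype_code, dtype=np.int8)
        if genotype_code == 2:  # heterozygous
            geno[:, :, 0] = 0
            geno[:, :, 1] = 1
        gm = GenotypeMatrix(["X_1"], ["X"], loci, {l: ("A", "C") for l in loci}, geno)
        cf = {
            "c1": {l: np.array([0.999, 0.001]) for l in loci},
            "c2": {l: np.array([0.001, 0.999]) for l in loci},
        }
        return gm, cf

    def test_matching_individual_q_to_one(self):
        gm, cf = self._fixed_cluster_gm(0)
        res = hyb.supervised_ancestry(gm, cf)
        assert res.q.iloc[0]["c1"] > 0.99
        assert res.classification.iloc[0] == "resident"

    def test_f1_individual_half_half_matches_grid_oracle(self):
        gm, cf = self._fixed_cluster_gm(2)
        res = hyb.supervised_ancestry(gm, cf)
        assert res.q.iloc[0]["c1"] == pytest.approx(0.5, abs=1e-3)
        # grid-search oracle over the simplex
        loci = gm.loci
        copies = [(l, c) for l in loci for c in (0, 1)]
        def loglik(q1):
            ll = 0.0
            for l, c in copies:
                ll += np.log(q1 * cf["c1"][l][c] + (1 - q1) * cf["c2"][l][c])
            return ll
        grid = np.linspace(0.001, 0.999, 999)
        best = grid[int(np.argmax([loglik(q) for q in grid]))]
        assert res.q.iloc[0]["c1"] == pytest.approx(best, abs=2e-3)

    def test_single_cluster_degenerate(self):
        gm, cf = self._fixed_cluster_gm(0)
        res = hyb.supervised_ancestry(gm, {"c1": cf["c1"]})
        assert res.q.iloc[0]["c1"] == 1.0


class TestClassifyQ:
    @pytest.mark.parametrize(
        "q,label",
        [(0.81, "resident"), (0.8, "admixed"), (0.5, "admixed"),
         (0.2, "admixed"), (0.19, "migrant")],
    )
    def test_thresholds(self, q, label):
        assert hyb.classify_q(q, None) == label
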