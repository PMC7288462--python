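import numpy as np
import pytest

from musselpipe import synthdata as sd
from musselpipe.datamodel import GenotypeMatrix

#: Seed for every scenario-based check in the suite.
STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: 12 sites x ~30 individuals x 54 SNPs."""
    sites, clines, profiles = sd.default_scenario(seed=STUDY_SEED)
    gm, ann, env, truth = sd.generate_study(sites, clines, profiles, seed=STUDY_SEED)
    return {
        "gm": gm,
        "ann": ann,
        "env": env,
        "truth": truth,
        "sites": sites,
        "clines": clines,
        "profiles": profiles,
        "refs": sd.reference_pops(sites),
    }


@pytest.fixture(scope="session")
def fixed_panel_study():
    """Variant of the default study with fully fixed diagnostic loci
    (characteristic alleles at frequency 1 in their taxon, 0 elsewhere)."""
    rng = np.random.default_rng(STUDY_SEED)
    profiles = sd.make_taxon_profiles(
        n_loci=54,
        n_diagnostic={"trossulus": 16, "edulis": 6, "galloprovincialis": 6},
        d_high=1.0,
        d_low=0.0,
        seed=rng,
        n_triallelic=2,
    )
    sites, clines, _ = sd.default_scenario(seed=STUDY_SEED)
    gm, ann, env, truth = sd.generate_study(sites, clines, profiles, seed=STUDY_SEED)
    return {
        "gm": gm,
        "truth": truth,
        "profiles": profiles,
        "refs": sd.reference_pops(sites),
    }


def make_two_pop_gm(genos_a, genos_b, alleles=("A", "C"), locus="L1"):
    """One-locus GenotypeMatrix from explicit genotype pair lists."""
    genos = list(genos_a) + list(genos_b)
    n = len(genos)
    geno = np.array(genos, dtype=np.int8).reshape(n, 1, 2)
    return GenotypeMatrix(
        individuals=[f"P1_{i}" for i in range(len(genos_a))]
        + [f"P2_{i}" for i in range(len(genos_b))],
        populations=["P1"] * len(genos_a) + ["P2"] * len(genos_b),
        loci=[locus],
        alleles={locus: tuple(alleles)},
        geno=geno,
    )


def make_one_pop_gm(genos, alleles=("A", "C"), locus="L1", pop="P1"):
    genos = list(genos)
    geno = np.array(genos, dtype=np.int8).reshape(len(genos), 1, 2)
    return GenotypeMatrix(
        individuals=[f"{pop}_{i}" for i in range(len(genos))],
        populations=[pop] * len(genos),
        loci=[locus],
        alleles={locus: tuple(alleles)},
        geno=geno,
    )
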