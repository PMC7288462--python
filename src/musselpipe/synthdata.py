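"""Synthetic three-taxon SNP study generator.

Emulates the sampling design of a North Atlantic blue-mussel survey:
multiple population samples of diploid individuals scored at a few dozen
mostly biallelic SNPs, three taxa with taxon-characteristic allele
frequencies (including near-fixed diagnostic panels), bimodal hybrid zones
and unimodal hybrid swarms, within-population homozygote excess, and
site-level environmental vectors in which the taxon balance follows a
logistic cline of one driving variable (salinity by default, with the
10%-90% transition inside 8-11 psu).

Everything is deterministic under a seed: a single root generator spawns
named substreams per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ENV_VARIABLES,
    MISSING,
    DataError,
    EnvTable,
    GenotypeMatrix,
    LocusAnnotation,
)
from .hybrids import class_genotype_frequency

TAXA = ("trossulus", "edulis", "galloprovincialis")


@dataclass
class TaxonProfile:
    """Per-locus allele frequencies of one taxon, with its diagnostic loci.

    ``loci`` and ``alleles`` are shared across the three profiles of a study.
    """

    taxon: str
    loci: list[str]
    alleles: dict[str, tuple[str, ...]]
    freqs: dict[str, np.ndarray]
    diagnostic_loci: list[str]
    characteristic_allele: dict[str, str]

    def __post_init__(self) -> None:
        for loc, f in self.freqs.items():
            if not np.isclose(f.sum(), 1.0):
                raise DataError(f"{self.taxon}/{loc}: frequencies must sum to 1")


@dataclass
class ClineSpec:
    """Logistic cline of the relative weight of taxon_b over taxon_a along
    one environmental variable: w_b(x) = 1 / (1 + exp(-(x - midpoint)/steepness))."""

    variable: str
    midpoint: float
    steepness: float
    taxon_a: str = "trossulus"
    taxon_b: str = "edulis"

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise DataError("cline steepness must be > 0")

    def weight_b(self, x: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(x - self.midpoint) / self.steepness)))


# -- site compositions -------------------------------------------------

@dataclass
class Pure:
    taxon: str


@dataclass
class BimodalMixture:
    """Mixture of parental and hybrid classes between taxon_a and taxon_b.

    ``p_a``/``p_b`` may be None, in which case the parental split follows a
    matching ClineSpec evaluated at the site's driving variable.
    """

    p_a: float | None = None
    p_b: float | None = None
    p_f1: float = 0.0
    p_backcross: float = 0.0
    taxon_a: str = "trossulus"
    taxon_b: str = "edulis"


@dataclass
class UnimodalSwarm:
    """Hybrid swarm: per-individual ancestry drawn around mean_hi."""

    mean_hi: float
    sd_hi: float
    taxon_a: str = "trossulus"
    taxon_b: str = "edulis"


@dataclass
class SiteSpec:
    code: str
    composition: Pure | BimodalMixture | UnimodalSwarm
    environment: dict[str, float]
    region: str
    n: int = 30
    f: float = 0.0           # within-population inbreeding for pure classes
    latitude: float = 55.0
    longitude: float = 10.0
    reference_taxon: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.f < 1:
            raise DataError(f"{self.code}: inbreeding f must lie in [0, 1)")


# ---------------------------------------------------------------------
# Taxon profiles
# ---------------------------------------------------------------------

def make_taxon_profiles(
    n_loci: int = 54,
    n_diagnostic: int | dict[str, int] = 16,
    d_high: float = 0.9,
    d_low: float = 0.1,
    seed: int | np.random.Generator | None = None,
    n_triallelic: int = 0,
    shared_beta: tuple[float, float] = (2.0, 2.0),
    taxon_divergence: float = 0.02,
) -> list[TaxonProfile]:
    """Build the three taxon allele-frequency profiles.

    Each taxon gets ``n_diagnostic`` loci (an int applies to every taxon; a
    dict gives per-taxon counts) whose characteristic allele has frequency
    >= ``d_high`` in that taxon and <= ``d_low`` in the other two, by
    construction.  Non-diagnostic loci draw an ancestral frequency from a
    shared Beta and diverge mildly between taxa (Balding-Nichols with
    ``taxon_divergence``) to mimic shared polymorphism.  Triallelic loci
    (if any) are placed among the non-diagnostic ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(n_diagnostic, int):
        diag_counts = {t: n_diagnostic for t in TAXA}
    else:
        diag_counts = {t: int(n_diagnostic.get(t, 0)) for t in TAXA}
    total_diag = sum(diag_counts.values())
    if total_diag > n_loci:
        raise DataError("more diagnostic loci requested than loci available")
    if not 0 <= d_low < d_high <= 1:
        raise DataError("need 0 <= d_low < d_high <= 1")
    n_neutral = n_loci - total_diag
    if n_triallelic > n_neutral:
        raise DataError("triallelic loci must fit among non-diagnostic loci")
    loci = [f"L{i+1:03d}" for i in range(n_loci)]
    alleles: dict[str, tuple[str, ...]] = {}
    freqs: dict[str, dict[str, np.ndarray]] = {t: {} for t in TAXA}
    diag_of: dict[str, list[str]] = {t: [] for t in TAXA}
    char: dict[str, dict[str, str]] = {t: {} for t in TAXA}
    order = iter(loci)
    for taxon in TAXA:
        for _ in range(diag_counts[taxon]):
            loc = next(order)
            syms = tuple(sorted(rng.choice(list("ACGT"), size=2, replace=False)))
            alleles[loc] = syms
            hi = rng.uniform(d_high, 1.0)
            los = {t: rng.uniform(0.0, d_low) for t in TAXA if t != taxon}
            ci = int(rng.integers(0, 2))
            for t in TAXA:
                p = hi if t == taxon else los[t]
                vec = np.empty(2)
                vec[ci] = p
                vec[1 - ci] = 1 - p
                freqs[t][loc] = vec
            diag_of[taxon].append(loc)
            char[taxon][loc] = syms[ci]
    remaining = list(order)
    tri_set = set(remaining[:n_triallelic])
    for loc in remaining:
        if loc in tri_set:
            syms = tuple(sorted(rng.choice(list("ACGT"), size=3, replace=False)))
            alleles[loc] = syms
            anc = rng.dirichlet([3.0, 3.0, 3.0])
            for t in TAXA:
                v = rng.dirichlet(anc * (1 - taxon_divergence) / taxon_divergence)
                freqs[t][loc] = v
        else:
            syms = tuple(sorted(rng.choice(list("ACGT"), size=2, replace=False)))
            alleles[loc] = syms
            anc = rng.beta(*shared_beta)
            F = taxon_divergence
            for t in TAXA:
                p = rng.beta(anc * (1 - F) / F, (1 - anc) * (1 - F) / F)
                p = float(np.clip(p, 0.01, 0.99))
                freqs[t][loc] = np.array([p, 1 - p])
    return [
        TaxonProfile(
            taxon=t,
            loci=loci,
            alleles=alleles,
            freqs=freqs[t],
            diagnostic_loci=diag_of[t],
            characteristic_allele=char[t],
        )
        for t in TAXA
    ]


# ---------------------------------------------------------------------
# Individual sampling
# ---------------------------------------------------------------------

def _inbred_genotype_probs(p: np.ndarray, f: float) -> np.ndarray:
    """Upper-triangular genotype probabilities with homozygote excess:
    P(aa) = p_a^2 + f p_a (1 - p_a); P(ab) = 2 p_a p_b (1 - f)."""
    k = len(p)
    probs = np.zeros((k, k))
    for i in range(k):
        probs[i, i] = p[i] ** 2 + f * p[i] * (1 - p[i])
        for j in range(i + 1, k):
            probs[i, j] = 2 * p[i] * p[j] * (1 - f)
    return probs


def sample_individual(
    hybrid_class: tuple,
    profiles: dict[str, TaxonProfile],
    f: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one individual's genotypes from its class's expected genotype
    distribution over all loci.

    ``hybrid_class`` is ``("pure", taxon)``, ``("F1"|"F2"|"BC_A"|"BC_B",
    taxon_a, taxon_b)`` or ``("swarm", taxon_a, taxon_b, ancestry)`` where
    ancestry in [0, 1] is the taxon_a genome fraction.  For pure classes the
    inbreeding coefficient ``f`` adds homozygote excess.
    """
    if not 0 <= f < 1:
        raise DataError("f must lie in [0, 1)")
    rng = rng or np.random.default_rng()
    kind = hybrid_class[0]
    any_prof = next(iter(profiles.values()))
    loci = any_prof.loci
    geno = np.empty((len(loci), 2), dtype=np.int8)
    for j, loc in enumerate(loci):
        k = len(any_prof.alleles[loc])
        if kind == "pure":
            p = profiles[hybrid_class[1]].freqs[loc]
            probs = _inbred_genotype_probs(p, f)
        elif kind == "swarm":
            _, ta, tb, theta = hybrid_class
            p = theta * profiles[ta].freqs[loc] + (1 - theta) * profiles[tb].freqs[loc]
            probs = _inbred_genotype_probs(p, 0.0)
        elif kind in ("F1", "F2", "BC_A", "BC_B"):
            _, ta, tb = hybrid_class
            pa = profiles[ta].freqs[loc]
            pb = profiles[tb].freqs[loc]
            cls = {"F1": "F1", "F2": "F2", "BC_A": "BC_A", "BC_B": "BC_B"}[kind]
            probs = class_genotype_frequency(cls, pa, pb)
        else:
            raise DataError(f"unknown class {hybrid_class!r}")
        flat = probs[np.triu_indices(k)]
        flat = flat / flat.sum()
        pick = rng.choice(len(flat), p=flat)
        ii, jj = np.triu_indices(k)
        geno[j] = (ii[pick], jj[pick])
    return geno


# ---------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------

def _site_classes(site: SiteSpec, clines: Sequence[ClineSpec], rng: np.random.Generator):
    comp = site.composition
    if isinstance(comp, Pure):
        return [("pure", comp.taxon)] * site.n
    if isinstance(comp, UnimodalSwarm):
        thetas = np.clip(rng.normal(comp.mean_hi, comp.sd_hi, size=site.n), 0.0, 1.0)
        return [("swarm", comp.taxon_a, comp.taxon_b, float(t)) for t in thetas]
    if isinstance(comp, BimodalMixture):
        p_a, p_b = comp.p_a, comp.p_b
        if p_a is None or p_b is None:
            cline = next(
                (
                    c for c in clines
                    if {c.taxon_a, c.taxon_b} == {comp.taxon_a, comp.taxon_b}
                ),
                None,
            )
            if cline is None:
                raise DataError(
                    f"site {site.code}: parental weights unset and no matching cline"
                )
            x = site.environment[cline.variable]
            w_b = cline.weight_b(x)
            w_a = 1.0 - w_b
            parental = max(0.0, 1.0 - comp.p_f1 - comp.p_backcross)
            p_a, p_b = parental * w_a, parental * w_b
        total = p_a + p_b + comp.p_f1 + comp.p_backcross
        if not np.isclose(total, 1.0, atol=1e-6):
            raise DataError(f"site {site.code}: composition weights sum to {total}")
        w_a_rel = p_a / (p_a + p_b) if (p_a + p_b) > 0 else 0.5
        classes = []
        draws = rng.choice(
            4, size=site.n, p=np.array([p_a, p_b, comp.p_f1, comp.p_backcross]) / total
        )
        for d in draws:
            if d == 0:
                classes.append(("pure", comp.taxon_a))
            elif d == 1:
                classes.append(("pure", comp.taxon_b))
            elif d == 2:
                classes.append(("F1", comp.taxon_a, comp.taxon_b))
            else:
                toward_a = rng.random() < w_a_rel
                classes.append(
                    ("BC_A" if toward_a else "BC_B", comp.taxon_a, comp.taxon_b)
                )
        return classes
    raise DataError(f"unknown composition {comp!r}")


def generate_study(
    sites: Sequence[SiteSpec],
    clines: Sequence[ClineSpec],
    profiles: Sequence[TaxonProfile],
    seed: int | None = None,
    missing_rate: float = 0.02,
    coding_fraction: float = 0.9,
):
    """Generate a full synthetic dataset plus a truth record.

    Returns ``(GenotypeMatrix, list[LocusAnnotation], EnvTable, truth)``;
    the truth record holds per-individual classes, per-site composition and
    cline parameters for parameter-recovery tests.
    """
    codes = [s.code for s in sites]
    if len(set(codes)) != len(codes):
        raise DataError("duplicate population codes in site list")
    root = np.random.default_rng(seed)
    prof_map = {p.taxon: p for p in profiles}
    loci = profiles[0].loci
    alleles = profiles[0].alleles
    individuals: list[str] = []
    populations: list[str] = []
    rows = []
    truth: dict = {
        "seed": seed,
        "clines": [asdict(c) for c in clines],
        "sites": {},
        "individual_class": {},
    }
    # named substream per site for reproducibility
    for site in sites:
        srng = np.random.default_rng(root.integers(2**31))
        classes = _site_classes(site, clines, srng)
        truth["sites"][site.code] = {
            "f": site.f,
            "n": site.n,
            "composition": type(site.composition).__name__,
            "class_counts": {},
        }
        for i, cls in enumerate(classes):
            ind = f"{site.code}_{i+1:03d}"
            individuals.append(ind)
            populations.append(site.code)
            f = site.f if cls[0] == "pure" else 0.0
            rows.append(sample_individual(cls, prof_map, f=f, rng=srng))
            label = cls[0] if cls[0] != "pure" else f"pure_{cls[1]}"
            truth["individual_class"][ind] = (
                label if cls[0] != "swarm" else f"swarm[{cls[3]:.3f}]"
            )
            cc = truth["sites"][site.code]["class_counts"]
            cc[label] = cc.get(label, 0) + 1
    geno = np.stack(rows)  # (n, L, 2)
    if missing_rate > 0:
        mask = root.random(size=(len(individuals), len(loci))) < missing_rate
        geno[mask] = MISSING
    gm = GenotypeMatrix(individuals, populations, list(loci), dict(alleles), geno)
    # annotation: coding/non-coding split, diagnostic flags from profiles
    anns = []
    n_coding = int(round(coding_fraction * len(loci)))
    coding_loci = set(root.choice(loci, size=n_coding, replace=False).tolist())
    for loc in loci:
        diag_for = None
        char = None
        for p in profiles:
            if loc in p.diagnostic_loci:
                diag_for = p.taxon
                char = p.characteristic_allele[loc]
                break
        coding = loc in coding_loci
        if coding:
            synonymy = "non-synonymous" if root.random() < 0.08 else "synonymous"
        else:
            synonymy = "n.a."
        anns.append(
            LocusAnnotation(
                locus=loc,
                alleles=alleles[loc],
                region_class="coding" if coding else "non-coding",
                synonymy=synonymy,
                diagnostic_for=diag_for,
                characteristic_allele=char,
            )
        )
    env_rows = {}
    for site in sites:
        env_rows[site.code] = {**site.environment, "region": site.region}
    env = EnvTable(pd.DataFrame.from_dict(env_rows, orient="index"))
    return gm, anns, env, truth


# ---------------------------------------------------------------------
# Default study scenario
# ---------------------------------------------------------------------

#: Default logistic cline of the trossulus/edulis balance along salinity:
#: midpoint 9.5 psu, steepness 0.6 puts the 10%-90% transition inside
#: 8-11 psu.
DEFAULT_CLINE = ClineSpec("salinity_psu", midpoint=9.5, steepness=0.6)


def make_environment(
    salinities: Sequence[float],
    rng: np.random.Generator,
    temp_ice_r: float = -0.87,
) -> list[dict[str, float]]:
    """Site environmental vectors: the driving salinity plus 11 weakly
    correlated noise variables, except a deliberate temperature-ice
    correlation (empirical r forced to ``temp_ice_r`` by construction)."""
    m = len(salinities)
    temp = rng.uniform(2.0, 18.0, size=m)
    t_std = (temp - temp.mean()) / temp.std()
    z = rng.normal(size=m)
    z -= z.mean()
    z -= (z @ t_std) / (t_std @ t_std) * t_std
    nz = np.linalg.norm(z)
    t_unit = t_std / np.linalg.norm(t_std)
    z_unit = z / nz if nz > 0 else z
    r = temp_ice_r
    ice_std = r * t_unit + np.sqrt(max(0.0, 1 - r**2)) * z_unit
    ice = 45.0 + 12.0 * ice_std * np.sqrt(m)
    ice = np.clip(ice, 0.0, 100.0)
    out = []
    for i in range(m):
        out.append(
            {
                "sea_ice_pct": float(ice[i]),
                "cloud_pct": float(rng.uniform(30, 90)),
                "wind_ms": float(rng.uniform(3, 12)),
                "solar_kj_m2_day": float(rng.uniform(6000, 16000)),
                "precip_mm": float(rng.uniform(300, 1500)),
                "temperature_c": float(temp[i]),
                "salinity_psu": float(salinities[i]),
                "swell_m": float(rng.uniform(0.2, 2.5)),
                "tide_cm": float(rng.uniform(5, 300)),
                "chlorophyll_mg_m3": float(rng.uniform(0.2, 8.0)),
                "nitrates_umol": float(rng.uniform(0.5, 12.0)),
                "phosphates_umol": float(rng.uniform(0.05, 1.5)),
            }
        )
    return out


def default_scenario(seed: int | None = 0):
    """The default study conditions: 12 sites along a 5-35 psu salinity
    gradient, ~30 diploid individuals each, 54 SNPs (16 trossulus-diagnostic,
    6 diagnostic for each other taxon, 2 triallelic), a trossulus/edulis
    cline with midpoint 9.5 psu, one bimodal contact site, one matched
    unimodal swarm site, reference sites for all three taxa, and one strongly
    inbred site (f = 0.6) emulating the large homozygote excesses seen in
    admixed Arctic samples.

    Returns ``(sites, clines, profiles)`` ready for :func:`generate_study`.
    """
    rng = np.random.default_rng(seed)
    profiles = make_taxon_profiles(
        n_loci=54,
        n_diagnostic={"trossulus": 16, "edulis": 6, "galloprovincialis": 6},
        d_high=0.95,
        d_low=0.05,
        seed=rng,
        n_triallelic=2,
    )
    sal = [5.0, 6.5, 8.0, 9.0, 9.4, 9.6, 10.0, 11.0, 13.0, 18.0, 25.0, 33.0]
    env = make_environment(sal, rng)
    B, NA, MED = "Baltic Sea", "North Atlantic Ocean", "Mediterranean and Black Seas"
    mix = BimodalMixture  # parental weights from the cline unless given
    sites = [
        SiteSpec("TR1", Pure("trossulus"), env[0], B, n=30, latitude=65.0,
                 reference_taxon="trossulus"),
        SiteSpec("SW1", UnimodalSwarm(mean_hi=0.97, sd_hi=0.03), env[1], B, n=30,
                 latitude=62.0),
        SiteSpec("CL1", mix(), env[2], B, n=30, latitude=60.0),
        SiteSpec("CL2", mix(p_f1=0.1, p_backcross=0.05), env[3], B, n=30, latitude=58.0),
        SiteSpec("BIM", mix(p_a=0.5, p_b=0.5), env[4], NA, n=34, latitude=56.0),
        SiteSpec("SW2", UnimodalSwarm(mean_hi=0.48, sd_hi=0.08), env[5], NA, n=30,
                 latitude=56.0),
        SiteSpec("CL3", mix(p_f1=0.1, p_backcross=0.05), env[6], NA, n=30, latitude=55.0),
        SiteSpec("CL4", mix(), env[7], NA, n=30, latitude=54.0),
        SiteSpec("CL5", mix(), env[8], NA, n=30, latitude=52.0),
        SiteSpec("ED1", Pure("edulis"), env[9], NA, n=30, latitude=50.0,
                 reference_taxon="edulis"),
        SiteSpec("INB", Pure("edulis"), env[10], NA, n=30, f=0.6, latitude=48.0),
        SiteSpec("GA1", Pure("galloprovincialis"), env[11], MED, n=30, latitude=40.0,
                 reference_taxon="galloprovincialis"),
    ]
    return sites, [DEFAULT_CLINE], profiles


def reference_pops(sites: Sequence[SiteSpec]) -> dict[str, list[str]]:
    """Reference-sample map taxon -> population codes."""
    out: dict[str, list[str]] = {}
    for s in sites:
        if s.reference_taxon:
            out.setdefault(s.reference_taxon, []).append(s.code)
    return out


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
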