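"""Per-population diversity statistics and Hardy-Weinberg testing.

Implements the column semantics of a classic SNP diversity table: proportion
of polymorphic loci (Po), observed and unbiased expected heterozygosity,
minor allele frequency, the inbreeding coefficient FIS with a one-sided
permutation test, exact (and Markov-chain) Hardy-Weinberg tests, and
Benjamini-Yekutieli FDR control.

"Polymorphic" means >= 2 alleles observed in the sample (no MAF floor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .datamodel import MISSING, DataError, GenotypeMatrix


@dataclass
class LocusPopStats:
    locus: str
    population: str
    allele_counts: np.ndarray
    maf: float
    ho: float
    he: float
    fis: float | None
    hwe_p: float
    polymorphic: bool


def allele_frequencies(gm: GenotypeMatrix, pop: str, locus: str) -> np.ndarray:
    """Allele frequencies over observed gene copies (missing excluded)."""
    counts = gm.allele_counts(pop, locus)
    total = counts.sum()
    if total == 0:
        raise DataError(f"no data for locus {locus} in population {pop}")
    return counts / total


def heterozygosities(gm: GenotypeMatrix, pop: str, locus: str) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity.

    HO is the fraction of heterozygous individuals among non-missing calls;
    HE is Nei's unbiased gene diversity ``(2n/(2n-1)) * (1 - sum p_i^2)``
    where n is the number of genotyped individuals.
    """
    j = gm.locus_col(locus)
    g = gm.geno[gm.pop_rows(pop), j, :]
    g = g[g[:, 0] != MISSING]
    n = len(g)
    if n < 2:
        raise DataError(f"need >= 2 genotyped individuals at {locus} in {pop}")
    ho = float((g[:, 0] != g[:, 1]).mean())
    counts = np.bincount(g.ravel(), minlength=len(gm.alleles[locus])).astype(float)
    p = counts / counts.sum()
    he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
    return ho, he


def fis(ho: float, he: float) -> float:
    """Inbreeding coefficient ``FIS = 1 - HO/HE``; undefined when HE = 0."""
    if he <= 0:
        raise DataError("FIS undefined for HE = 0")
    return 1.0 - ho / he


def fis_permutation_test(
    gm: GenotypeMatrix,
    pop: str,
    locus: str,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """One-sided permutation p-value for homozygote excess (FIS > 0).

    Allele copies are shuffled between individuals; p is the smoothed
    proportion of replicates with FIS >= the observed value.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    j = gm.locus_col(locus)
    g = gm.geno[gm.pop_rows(pop), j, :]
    g = g[g[:, 0] != MISSING]
    n = len(g)
    if n < 2 or len(np.unique(g)) < 2:
        raise DataError("FIS permutation test needs a polymorphic locus")
    obs_ho = float((g[:, 0] != g[:, 1]).mean())
    copies = g.ravel().copy()
    # HE is invariant under shuffling copies, so compare HO directly
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(copies)
        pairs = copies.reshape(n, 2)
        perm_ho = float((pairs[:, 0] != pairs[:, 1]).mean())
        if perm_ho <= obs_ho + 1e-12:  # FIS_perm >= FIS_obs
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def _log_table_prob(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Log conditional probability of a biallelic genotype table given its
    allele counts: ``n! nA! na! 2^het / (nAA! nAa! naa! (2n)!)``."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    return (
        gammaln(n + 1)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        + n_het * math.log(2.0)
        - gammaln(n_hom1 + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom2 + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_test(counts) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic locus.

    ``counts`` is ``(n_AA, n_Aa, n_aa)``.  The p-value sums the conditional
    probabilities (given allele counts) of all heterozygote configurations
    whose probability does not exceed that of the observed table.
    Monomorphic samples return 1 by convention.
    """
    n_hom1, n_het, n_hom2 = (int(c) for c in counts)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise DataError("negative genotype counts")
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    obs_lp = _log_table_prob(n_hom1, n_het, n_hom2)
    het_min = n_a % 2  # parity fixed by allele counts
    het_max = min(n_a, n_b)
    p = 0.0
    for h in range(het_min, het_max + 1, 2):
        lp = _log_table_prob((n_a - h) // 2, h, (n_b - h) // 2)
        if lp <= obs_lp + 1e-9:
            p += math.exp(lp)
    return min(p, 1.0)


def hwe_mc_test(
    counts,
    n_steps: int = 20_000,
    seed: int | np.random.Generator | None = None,
    burn_in: int = 1000,
) -> float:
    """Markov-chain Hardy-Weinberg test for 2- or 3-allele genotype tables.

    ``counts`` is a symmetric mapping/array of genotype counts indexed by
    unordered allele pairs, or the biallelic ``(n_AA, n_Aa, n_aa)`` triple.
    The chain swaps gene copies between random individuals (uniform over
    arrangements of the fixed gene copies, hence the exact conditional
    distribution over tables); p is the visit fraction of tables at most as
    probable as the observed one.  Agrees with :func:`hwe_exact_test` within
    Monte-Carlo error on biallelic inputs.
    """
    if n_steps <= burn_in:
        raise DataError("n_steps must exceed burn_in")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    table = _as_genotype_table(counts)
    if np.any(table < 0):
        raise DataError("negative genotype counts")
    # expand to per-individual gene copies
    pairs = [
        (i, j) for i in range(table.shape[0]) for j in range(i, table.shape[1])
        for _ in range(int(table[i, j]))
    ]
    n = len(pairs)
    if n == 0:
        raise DataError("empty genotype table")
    copies = np.array(pairs, dtype=np.int64)
    allele_counts = np.bincount(copies.ravel(), minlength=table.shape[0])
    if np.count_nonzero(allele_counts) < 2:
        return 1.0
    obs_lp = _table_log_prob_multi(table)
    cur_lp = obs_lp
    cur = table.astype(np.int64).copy()
    hits = 0
    kept = 0
    for step in range(n_steps):
        i1, i2 = rng.integers(0, n, size=2)
        s1, s2 = rng.integers(0, 2, size=2)
        if i1 == i2:
            pass  # self-swap keeps state; still counts as a step
        else:
            a = copies[i1, s1]
            b = copies[i2, s2]
            if a != b:
                g1_old = tuple(sorted(copies[i1]))
                g2_old = tuple(sorted(copies[i2]))
                copies[i1, s1], copies[i2, s2] = b, a
                g1_new = tuple(sorted(copies[i1]))
                g2_new = tuple(sorted(copies[i2]))
                for g in (g1_old, g2_old):
                    cur[g[0], g[1]] -= 1
                for g in (g1_new, g2_new):
                    cur[g[0], g[1]] += 1
                cur_lp = _table_log_prob_multi(cur)
        if step >= burn_in:
            kept += 1
            if cur_lp <= obs_lp + 1e-9:
                hits += 1
    return (hits + 1) / (kept + 1)


def _as_genotype_table(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim == 1 and arr.size == 3:
        n_aa, n_ab, n_bb = (int(c) for c in arr)
        return np.array([[n_aa, n_ab], [0, n_bb]], dtype=np.int64)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        # fold any lower-triangle entries into the upper triangle
        return (np.triu(arr) + np.tril(arr, -1).T).astype(np.int64)
    raise DataError("counts must be (n_AA,n_Aa,n_aa) or an upper-triangular table")


def _table_log_prob_multi(table: np.ndarray) -> float:
    """Log conditional probability of a k-allele genotype table given allele
    counts (Levene's distribution)."""
    k = table.shape[0]
    n = int(table.sum())
    het = int(table.sum() - np.trace(table))
    allele = np.zeros(k, dtype=np.int64)
    for i in range(k):
        for j in range(i, k):
            allele[i] += table[i, j]
            allele[j] += table[i, j]
    lp = (
        gammaln(n + 1)
        + float(np.sum(gammaln(allele + 1)))
        + het * math.log(2.0)
        - gammaln(2 * n + 1)
    )
    for i in range(k):
        for j in range(i, k):
            lp -= gammaln(int(table[i, j]) + 1)
    return float(lp)


def fdr_by(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Yekutieli step-up rejection flags at level ``alpha``.

    Valid under arbitrary dependence; rejections are always a subset of
    Benjamini-Hochberg rejections at the same level.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_by")
    return reject


@dataclass
class PopulationSummary:
    """One diversity-table row for a population."""

    population: str
    n: int
    po_pct: float                    # % polymorphic loci
    mean_ho: float                   # over polymorphic loci
    mean_he: float                   # over polymorphic loci
    mean_ho_all: float               # over all loci
    mean_he_all: float               # over all loci
    mean_maf: float                  # over polymorphic loci
    fis_multilocus: float | None     # 1 - sum(HO)/sum(HE) over polymorphic loci
    n_loci_out_of_hwe: int           # after FDR-BY within the population
    avg_gene_diversity: float        # mean HE over all loci
    mean_pairwise_diff: float        # mean allele mismatches between individuals


def locus_pop_stats(gm: GenotypeMatrix, pop: str, locus: str) -> LocusPopStats:
    counts = gm.allele_counts(pop, locus)
    total = counts.sum()
    if total == 0:
        raise DataError(f"no data at {locus} in {pop}")
    freqs = counts / total
    poly = int(np.count_nonzero(counts)) >= 2
    maf = float(np.sort(freqs)[-2]) if poly else 0.0
    try:
        ho, he = heterozygosities(gm, pop, locus)
    except DataError:
        ho, he = 0.0, 0.0
    f = fis(ho, he) if he > 0 else None
    if poly:
        gcounts = gm.genotype_counts(pop, locus)
        k = len(gm.alleles[locus])
        table = np.zeros((k, k), dtype=np.int64)
        for (a, b), c in gcounts.items():
            table[a, b] += c
        if k == 2:
            p_hwe = hwe_exact_test((table[0, 0], table[0, 1], table[1, 1]))
        else:
            p_hwe = hwe_mc_test(table, seed=0)
    else:
        p_hwe = 1.0
    return LocusPopStats(locus, pop, counts, maf, ho, he, f, p_hwe, poly)


def mean_pairwise_differences(gm: GenotypeMatrix, pop: str) -> float:
    """Average over individual pairs of per-locus allele mismatches summed
    across loci (loci missing in either individual are skipped).

    The mismatch between two unordered genotypes is the number of gene
    copies not shared (0, 1, or 2).
    """
    rows = gm.pop_rows(pop)
    n = len(rows)
    if n < 2:
        return 0.0
    g = gm.geno[rows]  # (n, L, 2)
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = g[i], g[j]
            ok = (gi[:, 0] != MISSING) & (gj[:, 0] != MISSING)
            if not ok.any():
                continue
            a, b = gi[ok], gj[ok]
            same_sorted = (a == b).all(axis=1)
            # shared copies under optimal matching of unordered pairs
            shared = np.zeros(ok.sum())
            shared[same_sorted] = 2
            rest = ~same_sorted
            if rest.any():
                ar, br = a[rest], b[rest]
                one = (
                    (ar[:, 0] == br[:, 0])
                    | (ar[:, 0] == br[:, 1])
                    | (ar[:, 1] == br[:, 0])
                    | (ar[:, 1] == br[:, 1])
                )
                shared[np.flatnonzero(rest)[one]] = 1
            total += float((2 - shared).sum())
            npairs += 1
    return total / npairs if npairs else 0.0


def population_summary(gm: GenotypeMatrix, pop: str, alpha: float = 0.05) -> PopulationSummary:
    """Diversity-table row: Po, HO/HE, MAF, multilocus FIS (ratio of
    averages), HWE failures after FDR-BY, average gene diversity and mean
    pairwise differences."""
    stats = [locus_pop_stats(gm, pop, loc) for loc in gm.loci]
    poly = [s for s in stats if s.polymorphic]
    po = 100.0 * len(poly) / len(stats)
    he_all = float(np.mean([s.he for s in stats]))
    ho_all = float(np.mean([s.ho for s in stats]))
    if poly:
        ho_p = float(np.mean([s.ho for s in poly]))
        he_p = float(np.mean([s.he for s in poly]))
        maf = float(np.mean([s.maf for s in poly]))
        sum_he = sum(s.he for s in poly)
        fis_ml = 1.0 - sum(s.ho for s in poly) / sum_he if sum_he > 0 else None
        rejected = fdr_by([s.hwe_p for s in poly], alpha=alpha)
        n_fail = int(rejected.sum())
    else:
        ho_p = he_p = maf = 0.0
        fis_ml = None
        n_fail = 0
    return PopulationSummary(
        population=pop,
        n=gm.pop_size(pop),
        po_pct=po,
        mean_ho=ho_p,
        mean_he=he_p,
        mean_ho_all=ho_all,
        mean_he_all=he_all,
        mean_maf=maf,
        fis_multilocus=fis_ml,
        n_loci_out_of_hwe=n_fail,
        avg_gene_diversity=he_all,
        mean_pairwise_diff=mean_pairwise_differences(gm, pop),
    )


def diversity_table(gm: GenotypeMatrix, alpha: float = 0.05):
    """Diversity-table rows for every population, as a DataFrame."""
    import pandas as pd

    rows = [population_summary(gm, p, alpha=alpha).__dict__ for p in gm.pop_codes]
    return pd.DataFrame(rows).set_index("population")
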