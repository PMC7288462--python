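"""Between-population structure: Weir-Cockerham FST with permutation tests,
an FST-outlier scan against a simulated neutral envelope, phase-free
genotypic linkage disequilibrium, neighbor-joining trees from FST distances,
and correspondence analysis.

The FST estimator is Weir & Cockerham's (1984) theta built from the a / b / c
variance components (among populations / among individuals within
populations / within individuals); the multilocus estimate is the ratio of
summed components.  Negative estimates are reported as computed and clamped
to zero only where a distance matrix is required.
"""

from __future__ import annotations

import io as _io
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, DataError, GenotypeMatrix


# ---------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------

def _wc_components(freqs: np.ndarray, hets: np.ndarray, sizes: np.ndarray):
    """Summed a, b, c components over alleles for one locus.

    Parameters are per-population allele frequencies ``freqs`` (r, k),
    per-population frequencies of heterozygotes carrying each allele
    ``hets`` (r, k), and genotyped sample sizes ``sizes`` (r,).
    """
    r = len(sizes)
    if r < 2:
        raise DataError("FST needs >= 2 populations with data")
    n_bar = sizes.mean()
    if n_bar <= 1:
        raise DataError("FST needs average sample size > 1")
    n_c = (sizes.sum() - (sizes**2).sum() / sizes.sum()) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for u in range(freqs.shape[1]):
        p = freqs[:, u]
        h = hets[:, u]
        p_bar = float((sizes * p).sum() / sizes.sum())
        s2 = float((sizes * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar))
        h_bar = float((sizes * h).sum() / sizes.sum())
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = n_bar / n_c * (s2 - (inner - h_bar / 4) / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _locus_pop_arrays(gm: GenotypeMatrix, pops, locus: str):
    j = gm.locus_col(locus)
    k = len(gm.alleles[locus])
    freqs, hets, sizes = [], [], []
    for pop in pops:
        g = gm.geno[gm.pop_rows(pop), j, :]
        g = g[g[:, 0] != MISSING]
        n = len(g)
        if n == 0:
            continue
        counts = np.bincount(g.ravel(), minlength=k).astype(float)
        freqs.append(counts / (2 * n))
        het_mask = g[:, 0] != g[:, 1]
        hu = np.zeros(k)
        for u in range(k):
            hu[u] = float(((g == u).sum(axis=1) == 1)[het_mask].sum()) / n if n else 0.0
        # simpler: individual heterozygous AND carries exactly one copy of u
        hets.append(hu)
        sizes.append(n)
    return np.array(freqs), np.array(hets), np.array(sizes, dtype=float)


def wc_fst(
    gm: GenotypeMatrix,
    pops=None,
    locus: str | None = None,
) -> float | tuple[pd.Series, float]:
    """Weir-Cockerham theta.

    With ``locus`` given, returns the per-locus estimate (NaN if the locus is
    monomorphic across the populations).  Otherwise returns
    ``(per_locus_series, multilocus_theta)`` where the multilocus estimate is
    ``sum(a) / sum(a+b+c)`` over loci; monomorphic loci contribute zero
    components.
    """
    pops = list(pops) if pops is not None else gm.pop_codes
    if locus is not None:
        freqs, hets, sizes = _locus_pop_arrays(gm, pops, locus)
        a, b, c = _wc_components(freqs, hets, sizes)
        denom = a + b + c
        return a / denom if abs(denom) > 1e-300 else float("nan")
    per_locus = {}
    A = D = 0.0
    for loc in gm.loci:
        freqs, hets, sizes = _locus_pop_arrays(gm, pops, loc)
        if len(sizes) < 2:
            per_locus[loc] = float("nan")
            continue
        a, b, c = _wc_components(freqs, hets, sizes)
        denom = a + b + c
        per_locus[loc] = a / denom if abs(denom) > 1e-300 else float("nan")
        A += a
        D += denom
    multi = A / D if abs(D) > 1e-300 else float("nan")
    return pd.Series(per_locus), multi


def fst_permutation_test(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed=None,
) -> tuple[float, float]:
    """Permutation p-value for the pairwise multilocus theta.

    Individuals are permuted between the two samples; p is the smoothed
    proportion of permuted estimates >= the observed one.  Returns
    ``(theta_obs, p)``.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rows_a, rows_b = gm.pop_rows(pop_a), gm.pop_rows(pop_b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise DataError("permutation test needs >= 2 individuals per population")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sub = gm.subset_pops([pop_a, pop_b])
    _, obs = wc_fst(sub, [pop_a, pop_b])
    n_a = len(rows_a)
    labels = np.array([pop_a] * n_a + [pop_b] * (sub.n_individuals - n_a))
    exceed = 0
    perm = sub
    for _ in range(n_perm):
        rng.shuffle(labels)
        perm = GenotypeMatrix(
            individuals=perm.individuals,
            populations=list(labels),
            loci=perm.loci,
            alleles=perm.alleles,
            geno=perm.geno,
        )
        _, theta = wc_fst(perm, [pop_a, pop_b])
        if np.isnan(theta):
            theta = 0.0
        if theta >= obs - 1e-12:
            exceed += 1
    return float(obs), (exceed + 1) / (n_perm + 1)


@dataclass
class FstMatrix:
    """Pairwise multilocus FST with permutation p-values, plus per-locus
    estimates across all populations."""

    theta: pd.DataFrame
    pvalues: pd.DataFrame
    per_locus: pd.Series
    multilocus: float

    def distance_matrix(self) -> pd.DataFrame:
        """Pairwise theta clamped to non-negative, zero diagonal."""
        d = self.theta.copy()
        d.values[d.values < 0] = 0.0
        np.fill_diagonal(d.values, 0.0)
        return d


def pairwise_fst(
    gm: GenotypeMatrix,
    n_perm: int = 1000,
    seed=None,
) -> FstMatrix:
    """All pairwise multilocus theta values with permutation p-values."""
    rng = np.random.default_rng(seed)
    pops = gm.pop_codes
    theta = pd.DataFrame(0.0, index=pops, columns=pops)
    pval = pd.DataFrame(1.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        t, p = fst_permutation_test(gm, a, b, n_perm=n_perm, seed=rng)
        theta.loc[a, b] = theta.loc[b, a] = t
        pval.loc[a, b] = pval.loc[b, a] = p
    per_locus, multi = wc_fst(gm)
    return FstMatrix(theta=theta, pvalues=pval, per_locus=per_locus, multilocus=multi)


# ---------------------------------------------------------------------
# FST outlier scan
# ---------------------------------------------------------------------

@dataclass
class OutlierScanResult:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    target_fst: float = float("nan")
    skipped: bool = False

    @property
    def outliers(self) -> list[str]:
        if self.skipped or self.table.empty:
            return []
        return list(self.table.index[self.table["outlier"]])


def _simulate_neutral_fst(
    target_fst: float, sizes: np.ndarray, n_sim: int, rng: np.random.Generator
):
    """Neutral per-locus (theta, total heterozygosity) under a symmetric
    island model: ancestral frequencies uniform, per-deme frequencies
    Balding-Nichols Beta with F = target FST, binomial genotype sampling at
    the observed sample sizes."""
    F = min(max(target_fst, 1e-4), 0.999)
    r = len(sizes)
    p_anc = rng.uniform(0.02, 0.98, size=n_sim)
    shape1 = p_anc * (1 - F) / F
    shape2 = (1 - p_anc) * (1 - F) / F
    p_dev = rng.beta(shape1[:, None], shape2[:, None], size=(n_sim, r))
    nAA = np.empty((n_sim, r))
    nAa = np.empty((n_sim, r))
    for i, n in enumerate(sizes.astype(int)):
        probs = np.stack(
            [p_dev[:, i] ** 2, 2 * p_dev[:, i] * (1 - p_dev[:, i]), (1 - p_dev[:, i]) ** 2],
            axis=1,
        )
        draws = rng.multinomial(n, probs)
        nAA[:, i], nAa[:, i] = draws[:, 0], draws[:, 1]
    n = sizes[None, :]
    p = (2 * nAA + nAa) / (2 * n)
    h = nAa / n
    # vectorized single-allele W-C components (biallelic symmetry doubles
    # every component, leaving theta unchanged)
    r_ = float(r)
    n_bar = n.mean()
    n_c = (n.sum() - (n**2).sum() / n.sum()) / (r_ - 1)
    w = n / n.sum()
    p_bar = (w * p).sum(axis=1)
    s2 = (n * (p - p_bar[:, None]) ** 2).sum(axis=1) / ((r_ - 1) * n_bar)
    h_bar = (w * h).sum(axis=1)
    inner = p_bar * (1 - p_bar) - (r_ - 1) / r_ * s2
    a = n_bar / n_c * (s2 - (inner - h_bar / 4) / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    denom = a + b + c
    ok = np.abs(denom) > 1e-12
    theta = np.where(ok, a / np.where(ok, denom, 1.0), np.nan)
    het_total = 1 - p_bar**2 - (1 - p_bar) ** 2
    return theta[ok], het_total[ok]


def fst_outlier_scan(
    gm: GenotypeMatrix,
    pops=None,
    n_sim: int = 30_000,
    alpha: float = 0.05,
    seed=None,
    n_bins: int = 10,
) -> OutlierScanResult:
    """Flag loci whose FST falls outside the simulated neutral envelope.

    Simulates ``n_sim`` neutral biallelic loci at the observed multilocus FST
    and sample sizes, bins them by total heterozygosity, and computes the
    (alpha/2, 1-alpha/2) FST envelope per bin; observed loci outside their
    bin's envelope are flagged.
    """
    if n_sim < 1000:
        raise DataError("n_sim must be >= 1000")
    pops = list(pops) if pops is not None else gm.pop_codes
    rng = np.random.default_rng(seed)
    per_locus, multi = wc_fst(gm, pops)
    if not np.isfinite(multi) or multi <= 0:
        warnings.warn("multilocus FST <= 0: outlier scan skipped")
        return OutlierScanResult(skipped=True, target_fst=multi)
    sizes = np.array([gm.pop_size(p) for p in pops], dtype=float)
    sim_theta, sim_het = _simulate_neutral_fst(multi, sizes, n_sim, rng)
    edges = np.quantile(sim_het, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    rows = []
    for loc in gm.loci:
        theta = per_locus[loc]
        freqs, _, szs = _locus_pop_arrays(gm, pops, loc)
        p_bar = (szs[:, None] * freqs).sum(axis=0) / szs.sum()
        het = 1 - float((p_bar**2).sum())
        if not np.isfinite(theta):
            rows.append((loc, theta, het, np.nan, np.nan, False))
            continue
        b = int(np.searchsorted(edges, het, side="right") - 1)
        b = min(max(b, 0), n_bins - 1)
        in_bin = sim_theta[(sim_het >= edges[b]) & (sim_het < edges[b + 1])]
        if len(in_bin) < 20:
            in_bin = sim_theta
        lo, hi = np.quantile(in_bin, [alpha / 2, 1 - alpha / 2])
        rows.append((loc, theta, het, lo, hi, bool(theta < lo or theta > hi)))
    table = pd.DataFrame(
        rows, columns=["locus", "fst", "het", "lower", "upper", "outlier"]
    ).set_index("locus")
    return OutlierScanResult(table=table, target_fst=multi)


# ---------------------------------------------------------------------
# Genotypic (phase-free) linkage disequilibrium
# ---------------------------------------------------------------------

def _genotype_codes(gm: GenotypeMatrix, pop: str, locus: str) -> np.ndarray:
    j = gm.locus_col(locus)
    g = gm.geno[gm.pop_rows(pop), j, :]
    code = np.where(g[:, 0] == MISSING, -1, g[:, 0] * 3 + g[:, 1])
    return code


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """G statistic of the contingency table of two integer code vectors."""
    xs = np.unique(x)
    ys = np.unique(y)
    table = np.zeros((len(xs), len(ys)))
    for i, xv in enumerate(xs):
        mask = x == xv
        for k, yv in enumerate(ys):
            table[i, k] = np.sum(mask & (y == yv))
    n = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return 2.0 * float(terms.sum())


def ld_pair_test(
    gm: GenotypeMatrix,
    pop: str,
    locus_a: str,
    locus_b: str,
    n_perm: int = 1000,
    seed=None,
) -> float:
    """Permutation p-value for genotypic (composite) LD between two loci.

    The statistic is the G statistic on the two-locus genotype contingency
    table; no gametic phase is assumed for double heterozygotes.  The null is
    generated by permuting single-locus genotypes across individuals.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = _genotype_codes(gm, pop, locus_a)
    y = _genotype_codes(gm, pop, locus_b)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if len(x) == 0 or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return 1.0
    obs = _g_statistic(x, y)
    yp = y.copy()
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(yp)
        if _g_statistic(x, yp) >= obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def ld_scan(
    gm: GenotypeMatrix,
    pop: str,
    loci=None,
    n_perm: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Genotypic LD over all unordered locus pairs (L loci -> L(L-1)/2 rows)."""
    rng = np.random.default_rng(seed)
    loci = list(loci) if loci is not None else list(gm.loci)
    rows = [
        (a, b, ld_pair_test(gm, pop, a, b, n_perm=n_perm, seed=rng))
        for a, b in itertools.combinations(loci, 2)
    ]
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "p"])


def n_ld_pairs(n_loci: int) -> int:
    """Number of unordered locus pairs scanned for L loci: L(L-1)/2."""
    return n_loci * (n_loci - 1) // 2


# ---------------------------------------------------------------------
# Neighbor-joining tree
# ---------------------------------------------------------------------

def nj_tree(distances: pd.DataFrame) -> str:
    """Saitou-Nei neighbor-joining tree from a (clamped) FST distance
    matrix; returns Newick text with population codes as leaf labels."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if distances.shape[0] < 3:
        raise DataError("NJ needs >= 3 populations")
    d = distances.to_numpy(dtype=float).copy()
    d[d < 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    dm = DistanceMatrix(d, ids=list(distances.index))
    tree = nj(dm)
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------

def pop_allele_count_table(gm: GenotypeMatrix, pops=None) -> pd.DataFrame:
    """Populations x (locus, allele) gene-copy count table for CA."""
    pops = list(pops) if pops is not None else gm.pop_codes
    cols = []
    data = []
    for pop in pops:
        row = []
        for loc in gm.loci:
            counts = gm.allele_counts(pop, loc)
            row.extend(counts)
        data.append(row)
    for loc in gm.loci:
        cols.extend(f"{loc}:{a}" for a in gm.alleles[loc])
    return pd.DataFrame(data, index=pops, columns=cols)


def individual_allele_count_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Individuals x (locus, allele) allele-copy count table for CA."""
    cols = []
    blocks = []
    for j, loc in enumerate(gm.loci):
        k = len(gm.alleles[loc])
        block = np.zeros((gm.n_individuals, k))
        g = gm.geno[:, j, :]
        for u in range(k):
            block[:, u] = (g == u).sum(axis=1)
        blocks.append(block)
        cols.extend(f"{loc}:{a}" for a in gm.alleles[loc])
    return pd.DataFrame(np.hstack(blocks), index=gm.individuals, columns=cols)


@dataclass
class CAResult:
    row_coords: pd.DataFrame      # rows x axes
    inertia_pct: np.ndarray       # per-axis inertia percentages, sums to 100


def correspondence_analysis(table: pd.DataFrame, n_axes: int | None = None) -> CAResult:
    """Chi-square-standardized SVD of a non-negative count table.

    Returns principal row coordinates and per-axis inertia percentages
    (summing to 100 over all retained axes).
    """
    N = table.to_numpy(dtype=float)
    keep_rows = N.sum(axis=1) > 0
    keep_cols = N.sum(axis=0) > 0
    N = N[np.ix_(keep_rows, keep_cols)]
    if N.size == 0 or N.sum() == 0:
        raise DataError("rank-0 count matrix")
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    pos = sv > 1e-12 * sv.max() if sv.max() > 0 else sv > -1
    U, sv = U[:, pos], sv[pos]
    if sv.size == 0:
        raise DataError("degenerate (rank-0 after centering) count matrix")
    inertia = sv**2
    pct = 100.0 * inertia / inertia.sum()
    coords = (U * sv[None, :]) / np.sqrt(r)[:, None]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        # percentages still reported over all axes
    idx = table.index[keep_rows]
    cols = [f"axis{i+1}" for i in range(coords.shape[1])]
    return CAResult(pd.DataFrame(coords, index=idx, columns=cols), pct)
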