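"""Diagnostic-allele panels, hybrid index, six-class hybrid assignment,
supervised ancestry fractions and q-threshold classification.

The hybrid index (HI) of an individual is the fraction of taxon-
characteristic allele copies it carries over a panel of diagnostic SNPs:
0 = "pure" alternative taxon (e.g. M. edulis), 1 = "pure" target taxon
(e.g. M. trossulus).  The six genotypic categories are the two parental
taxa, F1 and F2 hybrids, and the two first-generation backcrosses; their
expected genotype frequencies follow from gamete-pool algebra and yield a
plug-in posterior when parental allele frequencies are estimated from
reference samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, DataError, GenotypeMatrix

logger = logging.getLogger(__name__)

#: The six genotypic categories, in canonical order.
HYBRID_CLASSES = ("pure_A", "pure_B", "F1", "F2", "BC_A", "BC_B")


@dataclass
class DiagnosticPanel:
    """Ordered diagnostic loci with their characteristic alleles."""

    target_taxon: str
    loci: list[str]
    characteristic_allele: dict[str, str]
    reference_freq: dict[str, float]

    def __len__(self) -> int:
        return len(self.loci)


def _reference_freqs(gm: GenotypeMatrix, pops, locus: str) -> np.ndarray:
    j = gm.locus_col(locus)
    k = len(gm.alleles[locus])
    counts = np.zeros(k)
    for pop in pops:
        counts += gm.allele_counts(pop, locus)
    if counts.sum() == 0:
        return np.full(k, np.nan)
    return counts / counts.sum()


def select_diagnostic_panel(
    gm: GenotypeMatrix,
    reference_pops: dict[str, list[str]],
    target_taxon: str,
    d_high: float = 0.9,
    d_low: float = 0.2,
) -> DiagnosticPanel:
    """Select loci whose characteristic allele is near-fixed in the target
    taxon's reference samples and rare in the other taxa's.

    A locus qualifies when some allele has frequency >= ``d_high`` in the
    target references and <= ``d_low`` in each other taxon's references.
    """
    if target_taxon not in reference_pops:
        raise DataError(f"no reference populations declared for {target_taxon!r}")
    others = [t for t in reference_pops if t != target_taxon]
    loci, char, ref = [], {}, {}
    for locus in gm.loci:
        f_target = _reference_freqs(gm, reference_pops[target_taxon], locus)
        if np.any(np.isnan(f_target)):
            continue
        for u, sym in enumerate(gm.alleles[locus]):
            if f_target[u] < d_high:
                continue
            ok = True
            for t in others:
                f_other = _reference_freqs(gm, reference_pops[t], locus)
                if np.any(np.isnan(f_other)) or f_other[u] > d_low:
                    ok = False
                    break
            if ok:
                loci.append(locus)
                char[locus] = sym
                ref[locus] = float(f_target[u])
                break
    if not loci:
        raise DataError(
            "no loci satisfy the diagnostic thresholds; consider relaxing "
            f"d_high={d_high} / d_low={d_low}"
        )
    return DiagnosticPanel(target_taxon, loci, char, ref)


@dataclass
class HybridIndexResult:
    per_individual: pd.DataFrame   # columns: population, hi, n_loci
    per_population: pd.DataFrame   # columns: mean_hi, v_hi, n


def hybrid_index(gm: GenotypeMatrix, panel: DiagnosticPanel) -> HybridIndexResult:
    """HI per individual = characteristic-allele copies / (2 x panel loci
    scored); missing panel loci shrink the denominator.  Population mean HI
    and V_HI (variance, denominator n-1) exclude individuals with no scored
    panel loci."""
    if len(panel) == 0:
        raise DataError("empty diagnostic panel")
    cols = [gm.locus_col(l) for l in panel.loci]
    char_idx = np.array(
        [gm.alleles[l].index(panel.characteristic_allele[l]) for l in panel.loci]
    )
    g = gm.geno[:, cols, :]  # (n, P, 2)
    scored = g[:, :, 0] != MISSING
    copies = ((g == char_idx[None, :, None]) & scored[:, :, None]).sum(axis=(1, 2))
    denom = 2 * scored.sum(axis=1)
    hi = np.full(gm.n_individuals, np.nan)
    ok = denom > 0
    hi[ok] = copies[ok] / denom[ok]
    for i in np.flatnonzero(~ok):
        logger.warning(
            "individual %s has no scored panel loci; HI undefined", gm.individuals[i]
        )
    per_ind = pd.DataFrame(
        {
            "population": gm.populations,
            "hi": hi,
            "n_loci": scored.sum(axis=1),
        },
        index=gm.individuals,
    )
    rows = []
    for pop in gm.pop_codes:
        v = per_ind.loc[[gm.individuals[i] for i in gm.pop_rows(pop)], "hi"].dropna()
        rows.append(
            {
                "population": pop,
                "mean_hi": float(v.mean()) if len(v) else float("nan"),
                "v_hi": float(v.var(ddof=1)) if len(v) > 1 else float("nan"),
                "n": int(len(v)),
            }
        )
    return HybridIndexResult(per_ind, pd.DataFrame(rows).set_index("population"))


# ---------------------------------------------------------------------
# Six-class genotype frequencies and plug-in posterior
# ---------------------------------------------------------------------

def _gamete_pools(pa: np.ndarray, pb: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class (maternal, paternal) gamete allele-frequency vectors."""
    f1 = (pa + pb) / 2  # gamete pool of an F1 x F1 cross
    return {
        "pure_A": (pa, pa),
        "pure_B": (pb, pb),
        "F1": (pa, pb),
        "F2": (f1, f1),
        "BC_A": (pa, f1),
        "BC_B": (pb, f1),
    }


def class_genotype_frequency(
    hybrid_class: str,
    pa,
    pb,
    genotype: tuple[int, int] | None = None,
):
    """Expected genotype frequency under one of the six categories.

    ``pa``/``pb`` are parental allele-frequency vectors (a scalar is read as
    the frequency of the first of two alleles).  With ``genotype`` (an
    unordered pair of allele indices) returns that genotype's probability;
    otherwise returns the full symmetric genotype-probability matrix.
    """
    pa = np.array([pa, 1 - pa]) if np.isscalar(pa) else np.asarray(pa, dtype=float)
    pb = np.array([pb, 1 - pb]) if np.isscalar(pb) else np.asarray(pb, dtype=float)
    if hybrid_class not in HYBRID_CLASSES:
        raise DataError(f"unknown hybrid class {hybrid_class!r}")
    m, f = _gamete_pools(pa, pb)[hybrid_class]
    mat = np.outer(m, f)
    mat = (mat + mat.T) / 2  # unordered genotypes
    probs = np.triu(mat * 2) - np.diag(np.diag(mat))
    if genotype is None:
        return probs
    i, j = sorted(genotype)
    return float(probs[i, j])


def _smoothed_freqs(gm: GenotypeMatrix, pops, locus: str) -> np.ndarray:
    """Reference allele frequencies with Dirichlet(1) smoothing."""
    j = gm.locus_col(locus)
    k = len(gm.alleles[locus])
    counts = np.zeros(k)
    for pop in pops:
        counts += gm.allele_counts(pop, locus)
    return (counts + 1.0) / (counts.sum() + k)


@dataclass
class ClassPosterior:
    posterior: pd.DataFrame    # individuals x six classes
    map_class: pd.Series
    map_probability: pd.Series

    def population_report(self, gm: GenotypeMatrix) -> pd.DataFrame:
        """Per-population percentage of individuals MAP-assigned to each
        class (hybrid-identification table semantics)."""
        rows = []
        pops = pd.Series(list(gm.populations), index=gm.individuals)
        for pop in gm.pop_codes:
            sub = self.map_class[pops == pop]
            row = {"population": pop}
            for c in HYBRID_CLASSES:
                row[f"pct_{c}"] = 100.0 * float((sub == c).mean()) if len(sub) else 0.0
            rows.append(row)
        return pd.DataFrame(rows).set_index("population")


def assign_hybrid_classes(
    gm: GenotypeMatrix,
    reference_pops_a,
    reference_pops_b,
    loci=None,
    prior=None,
) -> ClassPosterior:
    """Plug-in posterior over the six genotypic categories.

    Parental allele frequencies are estimated from the two taxa's reference
    samples with Dirichlet(1) smoothing; loci are assumed independent; the
    prior over classes defaults to uniform.
    """
    loci = list(loci) if loci is not None else list(gm.loci)
    prior_vec = np.full(len(HYBRID_CLASSES), 1 / len(HYBRID_CLASSES))
    if prior is not None:
        prior_vec = np.asarray([prior[c] for c in HYBRID_CLASSES], dtype=float)
        prior_vec = prior_vec / prior_vec.sum()
    # per-locus class genotype log-probability tables
    tables = []
    cols = []
    for locus in loci:
        pa = _smoothed_freqs(gm, reference_pops_a, locus)
        pb = _smoothed_freqs(gm, reference_pops_b, locus)
        tabs = [class_genotype_frequency(c, pa, pb) for c in HYBRID_CLASSES]
        tables.append(tabs)
        cols.append(gm.locus_col(locus))
    loglik = np.zeros((gm.n_individuals, len(HYBRID_CLASSES)))
    for tabs, j in zip(tables, cols):
        g = gm.geno[:, j, :]
        ok = g[:, 0] != MISSING
        for ci in range(len(HYBRID_CLASSES)):
            probs = tabs[ci]
            vals = np.ones(gm.n_individuals)
            vals[ok] = probs[g[ok, 0], g[ok, 1]]
            loglik[:, ci] += np.log(np.maximum(vals, 1e-300))
    logpost = loglik + np.log(prior_vec)[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    df = pd.DataFrame(post, index=gm.individuals, columns=list(HYBRID_CLASSES))
    map_idx = post.argmax(axis=1)
    map_class = pd.Series(
        [HYBRID_CLASSES[i] for i in map_idx], index=gm.individuals, name="map_class"
    )
    map_p = pd.Series(post.max(axis=1), index=gm.individuals, name="map_probability")
    return ClassPosterior(df, map_class, map_p)


# ---------------------------------------------------------------------
# Supervised ancestry (admixture q) and q-threshold classification
# ---------------------------------------------------------------------

@dataclass
class AncestryResult:
    q: pd.DataFrame                # individuals x K clusters
    classification: pd.Series      # resident / admixed / migrant
    converged: pd.Series


def supervised_ancestry(
    gm: GenotypeMatrix,
    cluster_freqs: dict[str, dict[str, np.ndarray]],
    tol: float = 1e-8,
    max_iter: int = 5000,
    focal_cluster: str | None = None,
) -> AncestryResult:
    """Per-individual ancestry fractions q over K reference clusters by EM.

    ``cluster_freqs`` maps cluster label -> {locus -> allele-frequency
    vector}.  Each allele copy is a mixture observation with component
    probabilities ``q_k * p_k(allele)``; EM maximizes the likelihood over the
    simplex.  Classification against ``focal_cluster`` (default: first)
    uses the 0.2 / 0.8 thresholds.
    """
    clusters = list(cluster_freqs)
    K = len(clusters)
    if K < 1:
        raise DataError("need at least one cluster")
    focal = focal_cluster or clusters[0]
    if focal not in clusters:
        raise DataError(f"unknown focal cluster {focal!r}")
    # per-copy component probabilities for each individual
    qs = np.zeros((gm.n_individuals, K))
    converged = np.zeros(gm.n_individuals, dtype=bool)
    # assemble (n_copies, K) probability matrix per individual lazily
    locus_cols = {l: gm.locus_col(l) for l in gm.loci}
    pmats = []  # per locus: (K, k_alleles)
    for l in gm.loci:
        k = len(gm.alleles[l])
        mat = np.zeros((K, k))
        for ki, c in enumerate(clusters):
            f = np.asarray(cluster_freqs[c][l], dtype=float)
            mat[ki] = np.maximum(f, 1e-9)
        pmats.append(mat)
    for i in range(gm.n_individuals):
        probs = []  # per copy: length-K vector p_k(allele)
        for j, l in enumerate(gm.loci):
            g = gm.geno[i, locus_cols[l], :]
            if g[0] == MISSING:
                continue
            for copy in g:
                probs.append(pmats[j][:, copy])
        if not probs:
            qs[i] = 1.0 / K
            continue
        P = np.array(probs)  # (n_copies, K)
        if K == 1:
            qs[i, 0] = 1.0
            converged[i] = True
            continue
        q = np.full(K, 1.0 / K)
        for _ in range(max_iter):
            w = P * q[None, :]
            w /= w.sum(axis=1, keepdims=True)
            q_new = w.mean(axis=0)
            if np.max(np.abs(q_new - q)) < tol:
                q = q_new
                converged[i] = True
                break
            q = q_new
        else:
            logger.warning(
                "ancestry EM did not converge for %s", gm.individuals[i]
            )
        qs[i] = q
    qdf = pd.DataFrame(qs, index=gm.individuals, columns=clusters)
    labels = pd.Series(
        [classify_q(dict(zip(clusters, row)), focal) for row in qs],
        index=gm.individuals,
        name="classification",
    )
    return AncestryResult(qdf, labels, pd.Series(converged, index=gm.individuals))


def classify_q(q, focal_cluster) -> str:
    """Threshold classification of an ancestry vector.

    resident if q_focal > 0.8; admixed if 0.2 <= q_focal <= 0.8; migrant if
    q_focal < 0.2.
    """
    qf = float(q[focal_cluster]) if not np.isscalar(q) else float(q)
    if not 0 <= qf <= 1 + 1e-9:
        raise DataError("q must lie in [0, 1]")
    if qf > 0.8:
        return "resident"
    if qf >= 0.2:
        return "admixed"
    return "migrant"


def read_q_matrix(path) -> pd.DataFrame:
    """Import an externally computed q-matrix (TSV: one row per individual,
    K cluster columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    sums = df.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise DataError("q-matrix rows must sum to 1")
    return df


def cluster_freqs_from_references(
    gm: GenotypeMatrix, reference_pops: dict[str, list[str]]
) -> dict[str, dict[str, np.ndarray]]:
    """Smoothed per-cluster allele frequencies from reference samples."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for taxon, pops in reference_pops.items():
        out[taxon] = {l: _smoothed_freqs(gm, pops, l) for l in gm.loci}
    return out
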