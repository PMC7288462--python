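"""Independent oracles used by the test suite.

Each oracle derives its expected values by a different route than the
implementation it checks: exhaustive enumeration, dynamic programming over
random pairings, classical ANOVA mean squares, or path lengths on an
explicitly constructed tree.
"""

from functools import lru_cache

import numpy as np


# -- Hardy-Weinberg: distribution of the heterozygote count under random
#    pairing of the observed gene copies, by dynamic programming ----------

@lru_cache(maxsize=None)
def _pairing_het_dist(n_a: int, n_b: int) -> tuple[tuple[int, float], ...]:
    """P(#heterozygous pairs) when n_a A-copies and n_b a-copies are paired
    uniformly at random: sequentially pair the first unpaired copy with a
    uniformly random remaining copy."""
    if n_a + n_b == 0:
        return ((0, 1.0),)
    total = n_a + n_b
    out: dict[int, float] = {}
    if n_a > 0:
        # first unpaired copy is an A
        rest = total - 1
        if n_a >= 2:
            for h, p in _pairing_het_dist(n_a - 2, n_b):
                out[h] = out.get(h, 0.0) + p * (n_a - 1) / rest
        if n_b >= 1:
            for h, p in _pairing_het_dist(n_a - 1, n_b - 1):
                out[h + 1] = out.get(h + 1, 0.0) + p * n_b / rest
    else:
        for h, p in _pairing_het_dist(0, n_b - 2):
            out[h] = out.get(h, 0.0) + p
    return tuple(sorted(out.items()))


def hwe_exact_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional HWE p-value from the pairing distribution."""
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    dist = dict(_pairing_het_dist(n_a, n_b))
    p_obs = dist[n_het]
    return min(1.0, sum(p for p in dist.values() if p <= p_obs + 1e-12))


# -- Weir-Cockerham theta as a classical nested ANOVA ---------------------

def wc_anova_oracle(genotype_lists):
    """Theta from the nested random-effects ANOVA on allele indicators.

    ``genotype_lists``: one list per population of (a, b) allele-index
    pairs.  Components per allele: sigma_a = (MSP - MSI)/(2 n_c),
    sigma_b = (MSI - MSG)/2, sigma_c = MSG; theta sums components over
    alleles.  Returns NaN for monomorphic data.
    """
    pops = [np.asarray(g, dtype=float) for g in genotype_lists if len(g)]
    r = len(pops)
    sizes = np.array([len(g) for g in pops], dtype=float)
    n_tot = sizes.sum()
    n_c = (n_tot - (sizes**2).sum() / n_tot) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
    if len(alleles) < 2:
        return float("nan")
    num = den = 0.0
    for u in alleles:
        y = [np.mean(g == u, axis=1) for g in pops]  # per-individual mean (0,.5,1)
        p_i = [yi.mean() for yi in y]
        p_bar = float(np.concatenate(y).mean())
        ssp = sum(2 * n * (p - p_bar) ** 2 for n, p in zip(sizes, p_i))
        msp = ssp / (r - 1)
        ssi = sum(float((2 * (yi - p) ** 2).sum()) for yi, p in zip(y, p_i))
        msi = ssi / (n_tot - r)
        # within-individual SS: 0 for homozygous, 2*(0.5)^2 = 0.5 for het
        ssg = sum(float((0.5 * (yi * (1 - yi) * 4)).sum()) for yi in y)
        msg = ssg / n_tot
        sa = (msp - msi) / (2 * n_c)
        sb = (msi - msg) / 2
        sc = msg
        num += sa
        den += sa + sb + sc
    return num / den if abs(den) > 1e-300 else float("nan")


# -- additive tree distances ---------------------------------------------

def random_additive_matrix(n_taxa: int, rng: np.random.Generator):
    """Distance matrix of a random binary tree with random positive branch
    lengths, built by sequential taxon attachment; returns (labels, D)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    # adjacency with branch lengths over internal+leaf nodes
    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    next_internal = [n_taxa]
    add_edge(0, 1, float(rng.uniform(0.05, 1.0)))
    placed_edges = [(0, 1)]
    for leaf in range(2, n_taxa):
        a, b = placed_edges[int(rng.integers(len(placed_edges)))]
        w = edges[a].pop(b)
        edges[b].pop(a)
        mid = next_internal[0]
        next_internal[0] += 1
        cut = float(rng.uniform(0.2, 0.8)) * w
        add_edge(a, mid, cut)
        add_edge(mid, b, w - cut)
        add_edge(mid, leaf, float(rng.uniform(0.05, 1.0)))
        placed_edges.remove((a, b))
        placed_edges.extend([(a, mid), (mid, b), (mid, leaf)])
    # all-pairs shortest paths among leaves (tree: BFS with weights)
    def dists_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        return seen

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        di = dists_from(i)
        for j in range(n_taxa):
            D[i, j] = di[j]
    return labels, D


def newick_tip_distances(newick: str, labels):
    """Patristic tip-to-tip distances of a Newick tree (via scikit-bio)."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    n = len(labels)
    D = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = tips[a].distance(tips[b])
                D[i, j] = D[j, i] = d
    return D


# -- ANOSIM exact enumeration ---------------------------------------------

def anosim_r_oracle(D: np.ndarray, labels) -> float:
    """ANOSIM R computed from first principles (mean rank difference)."""
    labels = np.asarray(labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = np.array([D[i, j] for i, j in pairs])
    order = np.argsort(d, kind="stable")
    ranks = np.empty(len(d))
    # mid-ranks for ties
    sorted_d = d[order]
    k = 0
    while k < len(d):
        k2 = k
        while k2 + 1 < len(d) and sorted_d[k2 + 1] == sorted_d[k]:
            k2 += 1
        ranks[order[k : k2 + 1]] = (k + k2) / 2 + 1
        k = k2 + 1
    between = np.array([labels[i] != labels[j] for i, j in pairs])
    m = len(pairs)
    return float((ranks[between].mean() - ranks[~between].mean()) / (m / 2))


def anosim_exact_p_oracle(D: np.ndarray, labels) -> float:
    import itertools

    labels = list(labels)
    obs = anosim_r_oracle(D, labels)
    perms = set(itertools.permutations(labels))
    hits = sum(anosim_r_oracle(D, list(p)) >= obs - 1e-12 for p in perms)
    return hits / len(perms)


# -- Benjamini-Hochberg step-up (for the BY-subset property) --------------

def bh_reject_oracle(pvals, alpha=0.05):
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = int(np.max(np.flatnonzero(passed)))
        reject[order[: kmax + 1]] = True
    return reject
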