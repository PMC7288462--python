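"""Environment-genetics association: collinearity screen, per-locus BRT
models with the region factor, abrupt-transition detection along gradients,
and the coding vs non-coding comparison via ANOSIM / SIMPER on Bray-Curtis
dissimilarities of the per-locus importance profiles.

Environmental predictors are site-level constants replicated to allele
copies (two per genotyped individual); the response of each per-locus model
is which allele a copy carries (Bernoulli for two alleles, multinomial for
three).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import rankdata

from .brt import BRTConfig, cv_select_trees, fit_brt, partial_dependence, pseudo_r2, relative_influence
from .datamodel import ENV_VARIABLES, MISSING, DataError, EnvTable, GenotypeMatrix
from .pipeline import run_pipeline  # re-exported: part of this module's surface

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearityReport",
    "LocusModelSummary",
    "GroupComparison",
    "collinearity_screen",
    "locus_design",
    "per_locus_models",
    "detect_transition",
    "bray_curtis",
    "anosim",
    "simper",
    "coding_noncoding_comparison",
    "run_pipeline",
]


@dataclass
class CollinearityReport:
    r: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    exclusions: list[str] = field(default_factory=list)


def collinearity_screen(
    env: EnvTable, cutoff: float = 0.7, exclude: bool = False
) -> CollinearityReport:
    """Pairwise Pearson correlations of the environmental predictors over
    populations; pairs with |r| >= cutoff are flagged.  By default flagged
    pairs are retained with a warning (strong but tolerable collinearity,
    e.g. temperature vs ice cover, need not distort tree-based models);
    with ``exclude=True`` the second member of each flagged pair is dropped
    from the report's exclusion list."""
    if len(env.populations) < 3:
        raise DataError("collinearity screen needs >= 3 populations")
    r = env.numeric().corr(method="pearson")
    flagged = []
    exclusions: list[str] = []
    for a, b in itertools.combinations(r.columns, 2):
        val = r.loc[a, b]
        if np.isnan(val):
            continue
        if abs(val) >= cutoff:
            flagged.append((a, b, float(val)))
            warnings.warn(f"predictors {a} and {b} are strongly correlated (r={val:.2f})")
            if exclude and b not in exclusions:
                exclusions.append(b)
    return CollinearityReport(r=r, flagged=flagged, exclusions=exclusions)


# ---------------------------------------------------------------------
# Per-locus BRT models
# ---------------------------------------------------------------------

FEATURES = ENV_VARIABLES + ["region"]
REGION_FEATURE_INDEX = len(ENV_VARIABLES)


def locus_design(gm: GenotypeMatrix, env: EnvTable, locus: str):
    """Allele-copy design for one locus.

    Returns ``(X, y, groups)``: one row per observed allele copy with the 12
    environmental variables plus an integer-coded region, the allele index
    carried, and the population code (used for fold stratification).
    """
    j = gm.locus_col(locus)
    region_codes = {r: i for i, r in enumerate(sorted(set(env.frame["region"])))}
    X_rows, y, groups = [], [], []
    for pop in gm.pop_codes:
        row = env.row(pop)
        feat = [float(row[v]) for v in ENV_VARIABLES] + [float(region_codes[row["region"]])]
        g = gm.geno[gm.pop_rows(pop), j, :]
        g = g[g[:, 0] != MISSING]
        for a, b in g:
            for copy in (a, b):
                X_rows.append(feat)
                y.append(int(copy))
                groups.append(pop)
    return np.asarray(X_rows, dtype=float), np.asarray(y), np.asarray(groups)


@dataclass
class LocusModelSummary:
    locus: str
    loss: str
    n_trees: int
    pseudo_r2: float
    influence: pd.Series           # % per predictor, sums to 100
    transitions: dict[str, tuple[float, float] | None]
    region_class: str | None = None

    @property
    def region_influence(self) -> float:
        return float(self.influence.get("region", 0.0))


def fit_locus_model(
    gm: GenotypeMatrix,
    env: EnvTable,
    locus: str,
    config: BRTConfig | None = None,
    transition_vars=("salinity_psu",),
    transition_coverage: float = 0.8,
) -> LocusModelSummary | None:
    """CV-select and fit one per-locus model; None if the locus is
    monomorphic overall (skipped with a log entry)."""
    config = config or BRTConfig()
    X, y, groups = locus_design(gm, env, locus)
    if len(np.unique(y)) < 2:
        logger.info("locus %s monomorphic overall: model skipped", locus)
        return None
    k = len(gm.alleles[locus])
    loss = "bernoulli" if k == 2 else "multinomial"
    n_opt, curve, cv_pred = cv_select_trees(
        X, y, loss=loss, config=config, groups=groups,
        feature_names=FEATURES, cat_features={REGION_FEATURE_INDEX},
    )
    r2 = pseudo_r2(cv_pred, y)
    model = fit_brt(
        X, y, loss=loss, config=config, n_trees=max(n_opt, 1),
        feature_names=FEATURES, cat_features={REGION_FEATURE_INDEX},
    )
    model.n_trees_selected = max(n_opt, 1)
    model.cv_curve = curve
    infl = pd.Series(relative_influence(model), index=FEATURES)
    transitions: dict[str, tuple[float, float] | None] = {}
    minor = int(np.argmin(np.bincount(y, minlength=k)))  # rarer allele tracked
    for var in transition_vars:
        vi = FEATURES.index(var)
        lo, hi = X[:, vi].min(), X[:, vi].max()
        grid = np.linspace(lo, hi, 61)
        curve_pd = partial_dependence(model, vi, grid, class_index=minor)
        transitions[var] = detect_transition(grid, curve_pd, coverage=transition_coverage)
    return LocusModelSummary(
        locus=locus,
        loss=loss,
        n_trees=max(n_opt, 1),
        pseudo_r2=r2,
        influence=infl,
        transitions=transitions,
    )


def per_locus_models(
    gm: GenotypeMatrix,
    env: EnvTable,
    config: BRTConfig | None = None,
    loci=None,
    annotation_map=None,
    transition_vars=("salinity_psu",),
) -> list[LocusModelSummary]:
    """One BRT per locus (loss chosen by allele count), predictors = 12
    environmental variables + region."""
    for pop in gm.pop_codes:
        env.row(pop)  # raises if any population lacks an environment row
    out = []
    for locus in (loci if loci is not None else gm.loci):
        s = fit_locus_model(gm, env, locus, config=config, transition_vars=transition_vars)
        if s is None:
            continue
        if annotation_map and locus in annotation_map:
            s.region_class = annotation_map[locus].region_class
        out.append(s)
    return out


def model_summary_stats(summaries: list[LocusModelSummary]) -> dict:
    r2 = np.array([s.pseudo_r2 for s in summaries])
    return {
        "n_models": len(summaries),
        "frac_r2_above_0.4": float(np.mean(r2 > 0.4)) if len(r2) else float("nan"),
        "frac_r2_below_0.1": float(np.mean(r2 < 0.1)) if len(r2) else float("nan"),
        "max_region_influence": max((s.region_influence for s in summaries), default=float("nan")),
    }


def detect_transition(grid, curve, coverage: float = 0.8):
    """Shortest grid interval containing at least ``coverage`` of the
    curve's total variation; None (flagged) for a flat curve."""
    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if grid.size < 10:
        raise DataError("transition detection needs >= 10 grid points")
    d = np.abs(np.diff(curve))
    tv = d.sum()
    if tv <= 0:
        logger.info("flat partial-dependence curve: no transition interval")
        return None
    need = coverage * tv
    best = None
    csum = np.concatenate([[0.0], np.cumsum(d)])  # csum[j]-csum[i] over [i, j]
    i = 0
    for jj in range(1, len(grid)):
        while csum[jj] - csum[i + 1] >= need - 1e-12 and i + 1 < jj:
            i += 1
        if csum[jj] - csum[i] >= need - 1e-12:
            width = grid[jj] - grid[i]
            if best is None or width < best[0]:
                best = (width, grid[i], grid[jj])
    if best is None:
        return float(grid[0]), float(grid[-1])
    return float(best[1]), float(best[2])


# ---------------------------------------------------------------------
# Bray-Curtis, ANOSIM, SIMPER
# ---------------------------------------------------------------------

def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity ``sum|u-v| / sum(u+v)`` of two non-negative
    profiles; undefined (error) when both are all-zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DataError("profiles must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise DataError("profiles must be non-negative")
    if u.sum() + v.sum() == 0:
        raise DataError("Bray-Curtis undefined for two all-zero profiles")
    return float(_braycurtis(u, v))


def bray_curtis_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    n = len(profiles)
    D = np.zeros((n, n))
    vals = profiles.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(vals[i], vals[j])
    return pd.DataFrame(D, index=profiles.index, columns=profiles.index)


def _anosim_r(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(D[iu])
    within = labels[iu[0]] == labels[iu[1]]
    m = len(ranks)
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dissimilarity: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 999,
    seed=None,
    exact: bool = False,
) -> tuple[float, float]:
    """ANOSIM statistic R and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2) with M
    the number of object pairs.  The null is generated by permuting group
    labels; ``exact=True`` enumerates all distinct label assignments
    instead (feasible for small problems).
    """
    D = dissimilarity.to_numpy() if isinstance(dissimilarity, pd.DataFrame) else np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DataError("ANOSIM needs >= 2 groups")
    if counts.min() < 2:
        raise DataError("ANOSIM groups must each have >= 2 members")
    obs = _anosim_r(D, labels)
    if exact:
        perms = set(itertools.permutations(labels.tolist()))
        hits = sum(_anosim_r(D, np.array(p)) >= obs - 1e-12 for p in perms)
        return obs, hits / len(perms)
    rng = np.random.default_rng(seed)
    lab = labels.copy()
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(lab)
        if _anosim_r(D, lab) >= obs - 1e-12:
            exceed += 1
    return obs, (exceed + 1) / (n_perm + 1)


def simper(profiles: pd.DataFrame, labels) -> pd.DataFrame:
    """SIMPER decomposition of the mean between-group Bray-Curtis
    dissimilarity into per-variable contributions.

    Contribution of variable i = mean over between-group pairs of
    ``|u_i - v_i| / sum(u + v)``; contributions sum exactly to the mean
    between-group dissimilarity.  Output is ranked by contribution.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise DataError("SIMPER needs >= 2 groups")
    vals = profiles.to_numpy(dtype=float)
    n = len(vals)
    contrib = np.zeros(profiles.shape[1])
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                continue
            tot = vals[i].sum() + vals[j].sum()
            if tot == 0:
                raise DataError("Bray-Curtis undefined for two all-zero profiles")
            contrib += np.abs(vals[i] - vals[j]) / tot
            npairs += 1
    contrib /= npairs
    out = pd.DataFrame(
        {
            "contribution": contrib,
            "contribution_pct": 100.0 * contrib / contrib.sum() if contrib.sum() > 0 else 0.0,
        },
        index=profiles.columns,
    )
    return out.sort_values("contribution", ascending=False)


@dataclass
class GroupComparison:
    anosim_r: float
    p_value: float
    simper_table: pd.DataFrame
    mean_between_dissimilarity: float


def coding_noncoding_comparison(
    summaries: list[LocusModelSummary],
    n_perm: int = 999,
    seed=None,
) -> GroupComparison:
    """ANOSIM + SIMPER comparison of per-locus importance profiles between
    loci in coding vs non-coding regions (untransformed model results)."""
    rows = [s for s in summaries if s.region_class in ("coding", "non-coding")]
    if not rows:
        raise DataError("no annotated model summaries")
    profiles = pd.DataFrame(
        [s.influence for s in rows], index=[s.locus for s in rows]
    )
    labels = np.array([s.region_class for s in rows])
    D = bray_curtis_matrix(profiles)
    r, p = anosim(D, labels, n_perm=n_perm, seed=seed)
    table = simper(profiles, labels)
    return GroupComparison(
        anosim_r=r,
        p_value=p,
        simper_table=table,
        mean_between_dissimilarity=float(table["contribution"].sum()),
    )
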