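"""Core data types: genotype matrix, locus annotation, environment table.

Diploid SNP calls are stored as *unordered* allele pairs — gametic phase is
never assumed anywhere in the package.  Alleles are nucleotide symbols from
{A, C, G, T}; loci carry 2 or 3 alleles.  Missing calls are encoded as -1 in
the integer genotype array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ALLELE_SYMBOLS = ("A", "C", "G", "T")

MISSING = -1

#: The 12 site-level environmental variables used by the association models,
#: in canonical column order (units in parentheses).
ENV_VARIABLES = [
    "sea_ice_pct",        # sea-ice concentration (% coverage)
    "cloud_pct",          # total cloud amount (%)
    "wind_ms",            # wind speed (m/s)
    "solar_kj_m2_day",    # solar radiation (kJ m^-2 day^-1)
    "precip_mm",          # precipitation (mm)
    "temperature_c",      # sea water temperature (deg C)
    "salinity_psu",       # salinity (psu)
    "swell_m",            # swell height (m)
    "tide_cm",            # tide height (cm)
    "chlorophyll_mg_m3",  # chlorophyll-a (mg m^-3)
    "nitrates_umol",      # nitrate concentration (umol/L)
    "phosphates_umol",    # phosphate concentration (umol/L)
]

#: Fixed level set of the categorical `region` factor.
REGION_LEVELS = (
    "North Atlantic Ocean",
    "Baltic Sea",
    "Barents Sea",
    "Mediterranean and Black Seas",
)

_PERCENT_VARS = ("sea_ice_pct", "cloud_pct")


class DataError(ValueError):
    """Raised for malformed or internally inconsistent genetic data."""


@dataclass
class GenotypeMatrix:
    """Diploid SNP calls for individuals grouped into population samples.

    Parameters
    ----------
    individuals
        Individual IDs, one per row.
    populations
        Population code of each individual (parallel to ``individuals``).
    loci
        Locus IDs, one per column.
    alleles
        Mapping locus ID -> tuple of declared allele symbols (2 or 3).
    geno
        ``(n_individuals, n_loci, 2)`` int8 array of allele indices into the
        locus allele tuple; ``-1`` marks a missing call.  Pairs are stored
        sorted (unordered genotypes).
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    alleles: dict[str, tuple[str, ...]]
    geno: np.ndarray

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        n, L = len(self.individuals), len(self.loci)
        if n < 1 or L < 1:
            raise DataError("need at least one individual and one locus")
        if len(self.populations) != n:
            raise DataError("populations must parallel individuals")
        if self.geno.shape != (n, L, 2):
            raise DataError(f"geno shape {self.geno.shape} != {(n, L, 2)}")
        if len(set(self.individuals)) != n:
            raise DataError("duplicate individual IDs")
        for j, loc in enumerate(self.loci):
            alle = self.alleles.get(loc)
            if alle is None:
                raise DataError(f"locus {loc} lacks an allele declaration")
            if not 2 <= len(alle) <= 3:
                raise DataError(f"locus {loc}: allele count must be 2 or 3")
            col = self.geno[:, j, :]
            if col.max(initial=-1) >= len(alle):
                raise DataError(f"locus {loc}: allele index out of range")
        # missing is all-or-nothing per call; enforce sorted unordered pairs
        half = (self.geno == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise DataError("half-missing genotype call")
        self.geno = np.sort(self.geno, axis=2)
        self._pop_index: dict[str, np.ndarray] = {}
        for p in self.pop_codes:
            self._pop_index[p] = np.array(
                [i for i, q in enumerate(self.populations) if q == p], dtype=int
            )
        self._loc_index = {loc: j for j, loc in enumerate(self.loci)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_rows(self, pop: str) -> np.ndarray:
        """Row indices of individuals belonging to population ``pop``."""
        try:
            return self._pop_index[pop]
        except KeyError:
            raise DataError(f"unknown population code {pop!r}") from None

    def locus_col(self, locus: str) -> int:
        try:
            return self._loc_index[locus]
        except KeyError:
            raise DataError(f"unknown locus {locus!r}") from None

    def pop_size(self, pop: str) -> int:
        return len(self.pop_rows(pop))

    # -- counting helpers ------------------------------------------------
    def allele_counts(self, pop: str, locus: str) -> np.ndarray:
        """Observed gene-copy counts per declared allele (missing excluded)."""
        j = self.locus_col(locus)
        g = self.geno[self.pop_rows(pop), j, :].ravel()
        g = g[g != MISSING]
        return np.bincount(g, minlength=len(self.alleles[locus])).astype(float)

    def genotype_counts(self, pop: str, locus: str) -> dict[tuple[int, int], int]:
        """Counts of unordered genotypes ``(i <= j)``, missing excluded."""
        jcol = self.locus_col(locus)
        g = self.geno[self.pop_rows(pop), jcol, :]
        g = g[g[:, 0] != MISSING]
        out: dict[tuple[int, int], int] = {}
        for a, b in g:
            out[(int(a), int(b))] = out.get((int(a), int(b)), 0) + 1
        return out

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.locus_col(l) for l in loci]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            populations=list(self.populations),
            loci=list(loci),
            alleles={l: self.alleles[l] for l in loci},
            geno=self.geno[:, cols, :].copy(),
        )

    def subset_pops(self, pops: Sequence[str]) -> "GenotypeMatrix":
        rows = np.concatenate([self.pop_rows(p) for p in pops])
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in rows],
            populations=[self.populations[i] for i in rows],
            loci=list(self.loci),
            alleles=dict(self.alleles),
            geno=self.geno[rows].copy(),
        )

    def missing_fraction(self, locus: str) -> float:
        j = self.locus_col(locus)
        return float((self.geno[:, j, 0] == MISSING).mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and self.alleles == other.alleles
            and np.array_equal(self.geno, other.geno)
        )


@dataclass(frozen=True)
class LocusAnnotation:
    """Per-locus metadata: alleles, genomic context, diagnostic flags."""

    locus: str
    alleles: tuple[str, ...]
    region_class: str  # "coding" | "non-coding"
    synonymy: str = "n.a."  # "synonymous" | "non-synonymous" | "n.a."
    diagnostic_for: str | None = None
    characteristic_allele: str | None = None

    def __post_init__(self) -> None:
        if not 2 <= len(self.alleles) <= 3:
            raise DataError(f"{self.locus}: allele count must be 2 or 3")
        if self.region_class not in ("coding", "non-coding"):
            raise DataError(f"{self.locus}: bad region_class {self.region_class!r}")
        if self.synonymy not in ("synonymous", "non-synonymous", "n.a."):
            raise DataError(f"{self.locus}: bad synonymy {self.synonymy!r}")
        if (self.diagnostic_for is None) != (self.characteristic_allele is None):
            raise DataError(
                f"{self.locus}: characteristic_allele present iff diagnostic_for present"
            )
        if self.characteristic_allele is not None and (
            self.characteristic_allele not in self.alleles
        ):
            raise DataError(f"{self.locus}: characteristic allele not declared")


@dataclass(frozen=True)
class PopulationSample:
    """A sampled population: code, size, coordinates, biogeographic region."""

    code: str
    n_individuals: int
    latitude: float
    longitude: float
    region: str
    reference_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise DataError(f"{self.code}: n_individuals must be >= 1")
        if self.region not in REGION_LEVELS:
            raise DataError(
                f"{self.code}: region {self.region!r} not in {REGION_LEVELS}"
            )


class EnvTable:
    """Per-population environmental vectors plus the categorical region.

    Wraps a DataFrame indexed by population code with the 12 columns of
    :data:`ENV_VARIABLES` plus ``region``.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in ENV_VARIABLES + ["region"] if c not in frame.columns]
        if missing:
            raise DataError(f"environment table lacks columns: {missing}")
        if frame.index.has_duplicates:
            raise DataError("duplicate population codes in environment table")
        bad_region = set(frame["region"]) - set(REGION_LEVELS)
        if bad_region:
            raise DataError(f"unknown region levels: {sorted(bad_region)}")
        for c in _PERCENT_VARS:
            v = frame[c].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 100)):
                raise DataError(f"{c} must lie in [0, 100]")
        self.frame = frame[ENV_VARIABLES + ["region"]]
        self.frame.index.name = "population"

    @property
    def populations(self) -> list[str]:
        return list(self.frame.index)

    def row(self, pop: str) -> pd.Series:
        if pop not in self.frame.index:
            raise DataError(f"no environment row for population {pop!r}")
        return self.frame.loc[pop]

    def numeric(self) -> pd.DataFrame:
        """The 12 numeric environmental columns."""
        return self.frame[ENV_VARIABLES]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnvTable):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class ValidationReport:
    """Outcome of cross-checking genotype, annotation and environment data."""

    issues: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    per_locus_missingness: dict[str, float] = field(default_factory=dict)
    per_population_n: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues


def annotation_map(ann: Iterable[LocusAnnotation]) -> dict[str, LocusAnnotation]:
    out: dict[str, LocusAnnotation] = {}
    for a in ann:
        if a.locus in out:
            raise DataError(f"duplicate annotation for locus {a.locus}")
        out[a.locus] = a
    return out


def genotype_matrix_from_calls(
    individuals: Sequence[str],
    populations: Sequence[str],
    loci: Sequence[str],
    alleles: Mapping[str, Sequence[str]],
    calls: Mapping[tuple[str, str], tuple[str, str] | None],
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from symbolic per-(individual, locus) calls.

    ``calls`` maps (individual, locus) to an unordered pair of allele symbols
    or ``None`` for missing; absent keys are missing too.
    """
    allele_t = {l: tuple(alleles[l]) for l in loci}
    geno = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int8)
    for (ind, loc), pair in calls.items():
        if pair is None:
            continue
        i = list(individuals).index(ind)
        j = list(loci).index(loc)
        idx = []
        for sym in pair:
            if sym not in allele_t[loc]:
                raise DataError(f"allele {sym!r} not declared for locus {loc}")
            idx.append(allele_t[loc].index(sym))
        geno[i, j, :] = sorted(idx)
    return GenotypeMatrix(
        individuals=list(individuals),
        populations=list(populations),
        loci=list(loci),
        alleles=allele_t,
        geno=geno,
    )
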