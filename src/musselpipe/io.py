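"""Readers and writers: Genepop, wide-CSV genotypes, annotation and
environment TSV tables, plus dataset cross-validation.

Genepop dialect: a title line, one locus name per line (or a single
comma-separated line), ``POP`` separators, and individual lines
``id ,  0101 0102 ...`` with 2- or 3-digit allele codes where ``00``/``000``
is missing.  Numeric allele codes map to nucleotide symbols through a code
table (default ``01->A, 02->C, 03->G, 04->T``).

Wide CSV dialect: columns ``individual, population, <locus...>`` with
two-letter cells such as ``AC`` and ``--`` for missing; cells are unordered
("CA" == "AC").
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ENV_VARIABLES,
    MISSING,
    DataError,
    EnvTable,
    GenotypeMatrix,
    LocusAnnotation,
    ValidationReport,
)

DEFAULT_CODE_TABLE = {"01": "A", "02": "C", "03": "G", "04": "T"}

_MISSING_CSV = "--"


class ParseError(DataError):
    """Raised when an input file violates its declared format."""


def _pop_code_from_id(ind_id: str) -> str:
    """Population code = prefix up to the last underscore (else whole ID)."""
    return ind_id.rsplit("_", 1)[0] if "_" in ind_id else ind_id


def read_genepop(
    path: str | os.PathLike,
    code_table: Mapping[str, str] | None = None,
    pop_names: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read a Genepop file into a :class:`GenotypeMatrix`.

    Population codes are derived from the last individual ID of each POP
    block unless ``pop_names`` supplies an explicit sidecar mapping (one name
    per POP block, in file order).
    """
    code_table = dict(code_table or DEFAULT_CODE_TABLE)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise ParseError("file too short for Genepop format")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i].strip()
        if chunk:
            loci.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if not loci:
        raise ParseError("no locus names before first POP")
    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for lineno, raw in enumerate(body[i:], start=i + 2):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise ParseError(f"line {lineno}: genotype line before any POP")
        if "," not in line:
            raise ParseError(f"line {lineno}: missing ',' after individual ID")
        ind_id, rest = line.split(",", 1)
        fields = rest.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"line {lineno}: {len(fields)} genotype fields for "
                f"{len(loci)} declared loci"
            )
        current.append((ind_id.strip(), fields))
    if not blocks or not all(blocks):
        raise ParseError("empty POP block")

    # decode allele codes
    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    symbols_seen: dict[str, set[str]] = {l: set() for l in loci}
    decoded: list[list[tuple[str, str] | None]] = []
    for b, block in enumerate(blocks):
        pop = pop_names[b] if pop_names is not None else _pop_code_from_id(block[-1][0])
        for ind_id, fields in block:
            individuals.append(ind_id)
            populations.append(pop)
            row: list[tuple[str, str] | None] = []
            for loc, f in zip(loci, fields):
                if len(f) not in (4, 6) or not f.isdigit():
                    raise ParseError(f"bad genotype field {f!r} at locus {loc}")
                w = len(f) // 2
                c1, c2 = f[:w], f[w:]
                if int(c1) == 0 or int(c2) == 0:
                    if int(c1) != 0 or int(c2) != 0:
                        raise ParseError(f"half-missing genotype {f!r} at locus {loc}")
                    row.append(None)
                    continue
                syms = []
                for c in (c1, c2):
                    key = c[-2:].zfill(2)
                    if key not in code_table:
                        raise DataError(f"unknown allele code {c!r} at locus {loc}")
                    syms.append(code_table[key])
                symbols_seen[loc].update(syms)
                row.append((syms[0], syms[1]))
            decoded.append(row)
    if len(set(individuals)) != len(individuals):
        individuals = [f"{p}:{ind}" if individuals.count(ind) > 1 else ind
                       for p, ind in zip(populations, individuals)]
    alleles = {}
    for loc in loci:
        seen = sorted(symbols_seen[loc])
        if not seen:
            seen = ["A", "C"]  # fully missing column still needs 2 alleles
        elif len(seen) == 1:
            pool = [s for s in "ACGT" if s not in seen]
            seen = sorted(seen + [pool[0]])
        if len(seen) > 3:
            raise DataError(f"locus {loc}: more than 3 alleles observed")
        alleles[loc] = tuple(seen)
    geno = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int8)
    for irow, row in enumerate(decoded):
        for j, pair in enumerate(row):
            if pair is None:
                continue
            loc = loci[j]
            geno[irow, j, :] = sorted(alleles[loc].index(s) for s in pair)
    return GenotypeMatrix(individuals, populations, loci, alleles, geno)


def write_genepop(
    gm: GenotypeMatrix,
    path: str | os.PathLike,
    title: str = "musselpipe export",
    code_table: Mapping[str, str] | None = None,
) -> None:
    """Write a :class:`GenotypeMatrix` in the Genepop dialect."""
    code_table = dict(code_table or DEFAULT_CODE_TABLE)
    sym_to_code = {v: k for k, v in code_table.items()}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in gm.loci:
            fh.write(loc + "\n")
        for pop in gm.pop_codes:
            fh.write("POP\n")
            for i in gm.pop_rows(pop):
                fields = []
                for j, loc in enumerate(gm.loci):
                    a, b = gm.geno[i, j]
                    if a == MISSING:
                        fields.append("0000")
                    else:
                        syms = gm.alleles[loc]
                        fields.append(sym_to_code[syms[a]] + sym_to_code[syms[b]])
                fh.write(f"{gm.individuals[i]} ,  " + " ".join(fields) + "\n")


def read_csv_genotypes(path: str | os.PathLike) -> GenotypeMatrix:
    """Read the wide-CSV genotype dialect into a :class:`GenotypeMatrix`."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["individual", "population"]:
        raise ParseError("first two CSV columns must be individual, population")
    loci = list(df.columns[2:])
    if not loci:
        raise ParseError("no locus columns in CSV")
    alleles: dict[str, tuple[str, ...]] = {}
    for loc in loci:
        syms: set[str] = set()
        for cell in df[loc]:
            if pd.isna(cell) or cell == _MISSING_CSV:
                continue
            if len(cell) != 2:
                raise ParseError(f"bad genotype cell {cell!r} at locus {loc}")
            syms.update(cell)
        if len(syms) > 3:
            raise DataError(
                f"locus {loc}: more than 3 allele symbols observed: {sorted(syms)}"
            )
        out = sorted(syms)
        if not out:
            out = ["A", "C"]
        elif len(out) == 1:
            out = sorted(out + [s for s in "ACGT" if s not in out][:1])
        alleles[loc] = tuple(out)
    geno = np.full((len(df), len(loci), 2), MISSING, dtype=np.int8)
    for irow, (_, rec) in enumerate(df.iterrows()):
        for j, loc in enumerate(loci):
            cell = rec[loc]
            if pd.isna(cell) or cell == _MISSING_CSV:
                continue
            geno[irow, j, :] = sorted(alleles[loc].index(s) for s in cell)
    return GenotypeMatrix(
        individuals=list(df["individual"]),
        populations=list(df["population"]),
        loci=loci,
        alleles=alleles,
        geno=geno,
    )


def write_csv_genotypes(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the wide-CSV genotype dialect (round-trips bit-exactly)."""
    cols: dict[str, list[str]] = {
        "individual": list(gm.individuals),
        "population": list(gm.populations),
    }
    for j, loc in enumerate(gm.loci):
        syms = gm.alleles[loc]
        col = []
        for i in range(gm.n_individuals):
            a, b = gm.geno[i, j]
            col.append(_MISSING_CSV if a == MISSING else syms[a] + syms[b])
        cols[loc] = col
    pd.DataFrame(cols).to_csv(path, index=False)


# -- annotation and environment tables ----------------------------------

def write_annotation(ann: Iterable[LocusAnnotation], path: str | os.PathLike) -> None:
    rows = [
        {
            "locus": a.locus,
            "alleles": ",".join(a.alleles),
            "region_class": a.region_class,
            "synonymy": a.synonymy,
            "diagnostic_for": a.diagnostic_for or "",
            "characteristic_allele": a.characteristic_allele or "",
        }
        for a in ann
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | os.PathLike) -> list[LocusAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        out.append(
            LocusAnnotation(
                locus=r["locus"],
                alleles=tuple(r["alleles"].split(",")),
                region_class=r["region_class"],
                synonymy=r["synonymy"] or "n.a.",
                diagnostic_for=r["diagnostic_for"] or None,
                characteristic_allele=r["characteristic_allele"] or None,
            )
        )
    return out


def write_env_table(env: EnvTable, path: str | os.PathLike) -> None:
    env.frame.rename_axis("population").to_csv(path, sep="\t")


def read_env_table(path: str | os.PathLike) -> EnvTable:
    df = pd.read_csv(
        path, sep="\t", index_col="population", float_precision="round_trip"
    )
    return EnvTable(df)


def validate_dataset(
    gm: GenotypeMatrix,
    ann: Iterable[LocusAnnotation] | None = None,
    env: EnvTable | None = None,
) -> ValidationReport:
    """Cross-check locus IDs (genotypes vs annotation) and population codes
    (genotypes vs environment); report missingness and sample sizes.

    Annotation rows for loci absent from the genotype matrix are tolerated
    (warning only); genotype loci without annotation, or populations without
    an environment row, are failures.
    """
    rep = ValidationReport()
    rep.per_locus_missingness = {l: gm.missing_fraction(l) for l in gm.loci}
    rep.per_population_n = {p: gm.pop_size(p) for p in gm.pop_codes}
    if ann is not None:
        amap = {a.locus: a for a in ann}
        for loc in gm.loci:
            if loc not in amap:
                rep.issues.append(f"locus {loc} lacks an annotation row")
            elif set(amap[loc].alleles) != set(gm.alleles[loc]):
                rep.issues.append(
                    f"locus {loc}: annotation alleles {amap[loc].alleles} "
                    f"!= genotype alleles {gm.alleles[loc]}"
                )
        for loc in amap:
            if loc not in gm.loci:
                rep.warnings.append(f"annotation for absent locus {loc}")
    if env is not None:
        for pop in gm.pop_codes:
            if pop not in env.populations:
                rep.issues.append(f"population {pop} lacks environment row")
        for pop in env.populations:
            if pop not in gm.pop_codes:
                rep.warnings.append(f"environment row for absent population {pop}")
    return rep
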