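"""Domain types and plain-text readers/writers.

Containers for genotypes (minor-allele dosages with map metadata), pedigrees,
longitudinal phenotypes, kinship matrices and LD (r-squared) matrices, plus
parsers for PLINK-style text ``.ped``/``.map`` files, GEMMA-style square
kinship matrices, and the tab-separated results tables the analysis emits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("famassoc")

VALID_ALLELES = {"A", "C", "G", "T"}
MISSING_ALLELE = "0"

RESULT_COLUMNS = [
    "test_id", "snp1", "snp2", "chr1", "chr2",
    "phenotype", "beta", "se", "statistic", "df", "p",
]


class ParseError(ValueError):
    """A malformed input file (message names the offending line)."""


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic marker: identifier, map position and allele labels."""

    snp_id: str
    chromosome: int
    position: int
    allele_minor: str
    allele_major: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1 (1-based bp)")
        if self.chromosome < 1:
            raise ValueError(f"{self.snp_id}: chromosome must be a positive integer")
        if self.allele_minor == self.allele_major:
            raise ValueError(f"{self.snp_id}: minor and major alleles must differ")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage table.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for missing;
    it counts copies of the *minor* allele of each SNP.
    """

    individuals: list[tuple[str, str]]  # (family_id, individual_id)
    snps: list[SNPRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be in {0, 1, 2} or NaN")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_index(snp_id)]

    def flip_allele(self, snp_id: str) -> "GenotypeMatrix":
        """Recode one SNP to count the other allele (d -> 2 - d); involutive."""
        j = self.snp_index(snp_id)
        snps = list(self.snps)
        s = snps[j]
        snps[j] = SNPRecord(s.snp_id, s.chromosome, s.position,
                            s.allele_major, s.allele_minor)
        dosage = self.dosage.copy()
        dosage[:, j] = 2.0 - dosage[:, j]
        return GenotypeMatrix(list(self.individuals), snps, dosage)


@dataclass
class Pedigree:
    """Family / individual / parent structure.

    ``rows`` is a DataFrame with columns family_id, individual_id, father_id,
    mother_id (None for founders) and sex (1 = male, 2 = female). Validated to
    be acyclic with parents inside the same family.
    """

    rows: pd.DataFrame

    REQUIRED = ["family_id", "individual_id", "father_id", "mother_id", "sex"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        self.rows = self.rows.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        by_fam: dict[str, set[str]] = {}
        for fid, iid in zip(self.rows.family_id, self.rows.individual_id):
            by_fam.setdefault(str(fid), set()).add(str(iid))
        parents: dict[tuple[str, str], tuple] = {}
        for r in self.rows.itertuples(index=False):
            fid, iid = str(r.family_id), str(r.individual_id)
            for par in (r.father_id, r.mother_id):
                if par is not None and str(par) not in by_fam[fid]:
                    raise ValueError(
                        f"parent {par!r} of {iid!r} not in family {fid!r}")
            parents[(fid, iid)] = (r.father_id, r.mother_id)
        # acyclicity: iterative DFS over the parent relation
        state: dict[tuple[str, str], int] = {}
        for start in parents:
            if state.get(start):
                continue
            stack = [start]
            while stack:
                node = stack[-1]
                if state.get(node) == 2:
                    stack.pop()
                    continue
                state[node] = 1
                advanced = False
                fa, mo = parents[node]
                for par in (fa, mo):
                    if par is None:
                        continue
                    key = (node[0], str(par))
                    if state.get(key) == 1 and key in stack:
                        raise ValueError(f"pedigree cycle through {key}")
                    if state.get(key, 0) == 0:
                        stack.append(key)
                        advanced = True
                if not advanced:
                    state[node] = 2
                    stack.pop()

    @property
    def individuals(self) -> list[tuple[str, str]]:
        return [(str(f), str(i))
                for f, i in zip(self.rows.family_id, self.rows.individual_id)]

    def founders(self) -> list[tuple[str, str]]:
        m = self.rows.father_id.isna() if self.rows.father_id.dtype != object \
            else self.rows.father_id.isnull()
        return [(str(r.family_id), str(r.individual_id))
                for r in self.rows[m].itertuples(index=False)]


@dataclass
class PhenotypeTable:
    """Longitudinal phenotype + covariate records.

    One row per (individual, exam) with columns family_id, individual_id,
    exam (1-based), SBP, DBP, HTN, age, smoking, medication. Missing cells
    are NaN. SBP > DBP is enforced wherever both are present.
    """

    rows: pd.DataFrame

    REQUIRED = ["family_id", "individual_id", "exam",
                "SBP", "DBP", "HTN", "age", "smoking", "medication"]
    TRAITS = ["SBP", "DBP", "HTN", "MAP", "PP"]
    COVARIATES = ["age", "smoking", "medication"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        both = self.rows.SBP.notna() & self.rows.DBP.notna()
        if (self.rows.loc[both, "SBP"] <= self.rows.loc[both, "DBP"]).any():
            raise ValueError("SBP must exceed DBP wherever both are present")
        if (self.rows.exam < 1).any():
            raise ValueError("exam indices are 1-based")

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class KinshipMatrix:
    """Square symmetric relatedness matrix over a fixed individual ordering."""

    values: np.ndarray
    individuals: list[tuple[str, str]] | None = None
    estimator_tag: str = "RRM"  # {"RRM", "centered"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric (tol 1e-10)")
        if self.individuals is not None and len(self.individuals) != n:
            raise ValueError("individual labels do not match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class LDMatrix:
    """Square symmetric matrix of r-squared values over a SNP ordering."""

    r2: np.ndarray
    snps: list[SNPRecord]

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.snps)
        if self.r2.shape != (m, m):
            raise ValueError("LD matrix shape does not match SNP list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if ((self.r2 < 0) | (self.r2 > 1)).any():
            raise ValueError("r2 values must lie in [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must be 1")

    def index_of(self, snp_id: str) -> int:
        for j, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return j
        raise KeyError(f"SNP {snp_id!r} not in LD matrix")


# ---------------------------------------------------------------------------
# PLINK-style text .ped / .map
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path,
                 map_path: str | Path) -> tuple[GenotypeMatrix, Pedigree]:
    """Parse whitespace-delimited .ped/.map files into dosages + pedigree.

    The minor allele of each SNP is determined by in-sample allele frequency;
    ties are broken by taking the alphabetically first allele as minor. A
    genotype containing the symbol ``0`` is treated as missing.
    """
    map_rows: list[tuple[str, int, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}")
            chrom, snp_id, _gd, pos = parts
            map_rows.append((snp_id, int(chrom), int(pos)))
    m = len(map_rows)

    ped_meta: list[tuple[str, str, str | None, str | None, int]] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"for {m} SNPs, got {len(parts)}")
            fid, iid, fa, mo, sex, _pheno = parts[:6]
            alleles = parts[6:]
            for a in alleles:
                if a not in VALID_ALLELES and a != MISSING_ALLELE:
                    raise ParseError(
                        f"{ped_path}:{lineno}: invalid allele symbol {a!r}")
            ped_meta.append((fid, iid,
                             None if fa == "0" else fa,
                             None if mo == "0" else mo,
                             int(sex)))
            allele_rows.append(alleles)

    n = len(ped_meta)
    individuals = [(fid, iid) for fid, iid, *_ in ped_meta]
    a1 = np.array([[row[2 * j] for j in range(m)] for row in allele_rows],
                  dtype="U1") if n else np.empty((0, m), dtype="U1")
    a2 = np.array([[row[2 * j + 1] for j in range(m)] for row in allele_rows],
                  dtype="U1") if n else np.empty((0, m), dtype="U1")

    snps: list[SNPRecord] = []
    dosage = np.full((n, m), np.nan)
    for j, (snp_id, chrom, pos) in enumerate(map_rows):
        c1, c2 = a1[:, j], a2[:, j]
        present = (c1 != MISSING_ALLELE) & (c2 != MISSING_ALLELE)
        counts: dict[str, int] = {}
        for arr in (c1[present], c2[present]):
            for sym, cnt in zip(*np.unique(arr, return_counts=True)):
                counts[str(sym)] = counts.get(str(sym), 0) + int(cnt)
        if len(counts) > 2:
            raise ParseError(f"SNP {snp_id} has more than two alleles")
        if not counts:
            minor, major = "A", "C"  # entirely missing: placeholder labels
        elif len(counts) == 1:
            (only,) = counts
            minor = only
            major = next(a for a in sorted(VALID_ALLELES) if a != only)
        else:
            (x, cx), (y, cy) = sorted(counts.items())
            # alphabetical sort first -> ties give the alphabetically first as minor
            minor, major = (x, y) if cx <= cy else (y, x)
        snps.append(SNPRecord(snp_id, chrom, pos, minor, major))
        d = (c1 == minor).astype(float) + (c2 == minor).astype(float)
        d[~present] = np.nan
        dosage[:, j] = d

    ped = Pedigree(pd.DataFrame(
        ped_meta,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]))
    return GenotypeMatrix(individuals, snps, dosage), ped


def write_ped_map(genotypes: GenotypeMatrix, pedigree: Pedigree,
                  ped_path: str | Path, map_path: str | Path) -> None:
    """Emit .ped/.map text files (inverse of :func:`read_ped_map`)."""
    with open(map_path, "w") as fh:
        for s in genotypes.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    meta = {(str(r.family_id), str(r.individual_id)): r
            for r in pedigree.rows.itertuples(index=False)}
    with open(ped_path, "w") as fh:
        for i, key in enumerate(genotypes.individuals):
            r = meta[key]
            fields = [key[0], key[1],
                      str(r.father_id) if r.father_id is not None else "0",
                      str(r.mother_id) if r.mother_id is not None else "0",
                      str(int(r.sex)), "-9"]
            for j, s in enumerate(genotypes.snps):
                d = genotypes.dosage[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    k = int(d)
                    fields += [s.allele_minor] * k + [s.allele_major] * (2 - k)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GEMMA-style kinship files, LD files, results tables
# ---------------------------------------------------------------------------

def write_kinship(matrix: KinshipMatrix, path: str | Path) -> None:
    """Write a plain n x n whitespace matrix (GEMMA ``-k`` style, no header)."""
    np.savetxt(path, matrix.values, fmt="%.12g")


def read_kinship(path: str | Path, estimator_tag: str = "RRM") -> KinshipMatrix:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                rows.append([float(x) for x in line.split()])
    if not rows:
        raise ParseError(f"{path}: empty kinship file")
    n = len(rows)
    widths = {len(r) for r in rows}
    if widths != {n}:
        raise ParseError(
            f"{path}: expected a square {n}x{n} matrix, got row widths {sorted(widths)}")
    return KinshipMatrix(np.array(rows), estimator_tag=estimator_tag)


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    """TSV with SNP ids as header row and first column."""
    ids = [s.snp_id for s in ld.snps]
    df = pd.DataFrame(ld.r2, index=ids, columns=ids)
    meta = pd.DataFrame(
        {"snp_id": ids,
         "chromosome": [s.chromosome for s in ld.snps],
         "position": [s.position for s in ld.snps],
         "allele_minor": [s.allele_minor for s in ld.snps],
         "allele_major": [s.allele_major for s in ld.snps]})
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index_label="snp_id")
        fh.write("#MAP\n")
        meta.to_csv(fh, sep="\t", index=False)


def read_ld(path: str | Path) -> LDMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        split = lines.index("#MAP")
    except ValueError:
        raise ParseError(f"{path}: missing #MAP section") from None
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(lines[:split])), sep="\t", index_col=0)
    meta = pd.read_csv(StringIO("\n".join(lines[split + 1:])), sep="\t")
    snps = [SNPRecord(str(r.snp_id), int(r.chromosome), int(r.position),
                      str(r.allele_minor), str(r.allele_major))
            for r in meta.itertuples(index=False)]
    return LDMatrix(df.to_numpy(), snps)


def write_results(rows: Iterable[dict], path: str | Path) -> None:
    """Write association / interaction results as a fixed-column TSV."""
    records = []
    for r in rows:
        records.append({c: r.get(c, "") for c in RESULT_COLUMNS})
    df = pd.DataFrame(records, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
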