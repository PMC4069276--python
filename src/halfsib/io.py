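"""Readers, writers and validation for genotype, SNP-map and pedigree files.

All downstream algorithms consume a :class:`GenotypeMatrix` whose columns are
aligned with a :class:`SnpMap`.  Genotypes are coded 0/1/2 (count of the
reference allele) with 9 for missing.  Only the *order* of map positions is
ever used by the algorithms; positions are 1-based base pairs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GENOTYPES = frozenset({0, 1, 2, 9})
MISSING = 9
UNKNOWN_PARENT = "0"


class HalfsibError(Exception):
    """Base class for package errors."""


class ParseError(HalfsibError):
    """Malformed input file content."""


class ValidationError(HalfsibError):
    """Structurally valid input violating a domain invariant."""


def _natural_key(s: str):
    """Sort key treating embedded integers numerically ('2' < '10')."""
    return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", str(s)))


def _detect_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return r"\s+"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SnpMap:
    """SNP map: name, chromosome and base-pair position, in canonical order.

    Canonical order sorts by (chromosome, position) with natural chromosome
    ordering; ``load_permutation`` records, as 0-based indices into the input
    order, how rows were rearranged so genotype columns can be permuted
    identically.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    load_permutation: np.ndarray | None = None
    was_resorted: bool = False

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if len(self.snp_id) != len(set(self.snp_id)):
            ids, counts = np.unique(self.snp_id.astype(str), return_counts=True)
            dup = ids[counts > 1].tolist()
            raise ValidationError(f"duplicated snp_id(s): {dup[:5]}")
        if (self.position_bp < 0).any():
            raise ValidationError("negative base-pair positions")

    def __len__(self) -> int:
        return len(self.snp_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpMap":
        """Build from a 3-column frame (snp, chrom, pos); canonically sorts."""
        snp = df.iloc[:, 0].astype(str).to_numpy()
        chrom = df.iloc[:, 1].astype(str).to_numpy()
        try:
            pos = df.iloc[:, 2].astype(np.int64).to_numpy()
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-integer map position: {exc}") from exc
        order = sorted(
            range(len(snp)), key=lambda i: (_natural_key(chrom[i]), pos[i], snp[i])
        )
        perm = np.asarray(order, dtype=np.int64)
        resorted = not np.array_equal(perm, np.arange(len(snp)))
        if resorted:
            warnings.warn("map not in canonical order; rows were re-sorted")
        m = cls(snp[perm], chrom[perm], pos[perm])
        m.load_permutation = perm
        m.was_resorted = resorted
        for ch in np.unique(m.chromosome):
            p = m.position_bp[m.chromosome == ch]
            if (np.diff(p) <= 0).any():
                raise ValidationError(
                    f"positions on chromosome {ch} not strictly increasing after sort"
                )
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )

    def chromosomes(self) -> list[str]:
        """Chromosome names in canonical (natural) order."""
        return sorted(set(self.chromosome), key=_natural_key)

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous column ranges per chromosome (map is canonically sorted)."""
        out: dict[str, slice] = {}
        for ch in self.chromosomes():
            idx = np.flatnonzero(self.chromosome == ch)
            out[ch] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out


@dataclass
class GenotypeMatrix:
    """Individuals x SNP integer matrix in {0,1,2,9}, column-aligned to a map."""

    individual_ids: list[str]
    values: np.ndarray
    snp_ids: list[str] | None = None

    def __post_init__(self):
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be 2-dimensional")
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValidationError("row count does not match number of individual ids")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dup = {i for i in self.individual_ids if self.individual_ids.count(i) > 1}
            raise ValidationError(f"duplicate individual id(s): {sorted(dup)}")
        bad = ~np.isin(self.values, list(VALID_GENOTYPES))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"invalid genotype {int(self.values[r, c])} at "
                f"(row {self.individual_ids[r]}, column {c})"
            )
        if self.snp_ids is not None and len(self.snp_ids) != self.values.shape[1]:
            raise ValidationError("snp_ids length does not match column count")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_individuals(self, ids_or_idx) -> "GenotypeMatrix":
        if len(ids_or_idx) and isinstance(ids_or_idx[0], str):
            lookup = {v: i for i, v in enumerate(self.individual_ids)}
            idx = [lookup[i] for i in ids_or_idx]
        else:
            idx = list(ids_or_idx)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx], self.values[idx], self.snp_ids
        )

    def subset_snps(self, cols) -> "GenotypeMatrix":
        snp_ids = None
        if self.snp_ids is not None:
            snp_ids = list(np.asarray(self.snp_ids, dtype=object)[cols])
        return GenotypeMatrix(self.individual_ids, self.values[:, cols], snp_ids)


@dataclass
class PedigreeTable:
    """Individual -> sire records; sire '0' (or empty) means unknown."""

    individual_id: list[str]
    sire_id: list[str]

    def __post_init__(self):
        self.individual_id = [str(i) for i in self.individual_id]
        self.sire_id = [
            UNKNOWN_PARENT
            if s is None or str(s).strip() in ("", "0", "NA", "nan", "None")
            else str(s)
            for s in self.sire_id
        ]
        if len(self.individual_id) != len(self.sire_id):
            raise ValidationError("individual/sire column length mismatch")
        if len(set(self.individual_id)) != len(self.individual_id):
            dup = {i for i in self.individual_id if self.individual_id.count(i) > 1}
            raise ValidationError(f"duplicate individual id(s) in pedigree: {sorted(dup)}")
        for ind, sire in zip(self.individual_id, self.sire_id):
            if ind == sire:
                raise ValidationError(f"individual {ind!r} recorded as its own sire")

    def __len__(self) -> int:
        return len(self.individual_id)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.individual_id, self.sire_id))

    def known_pairs(self) -> list[tuple[str, str]]:
        return [
            (i, s)
            for i, s in zip(self.individual_id, self.sire_id)
            if s != UNKNOWN_PARENT
        ]


@dataclass
class AlignedBundle:
    """Genotypes, map and (optional) pedigree validated against each other."""

    genotypes: GenotypeMatrix
    snp_map: SnpMap
    pedigree: PedigreeTable | None
    chromosome_slices: dict[str, slice] = field(default_factory=dict)
    flagged_pedigree_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path, dialect: str = "matrix", sep: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix.

    ``matrix``: header row of SNP ids (first field is an id-column label or
    blank), one row per individual with the id in the first column.
    ``plink_ped``: PLINK .ped with two allele columns per SNP; the first
    allele seen per SNP becomes the reference counted by 0/1/2.
    """
    if dialect == "plink_ped":
        return _read_plink_ped(path)
    if dialect != "matrix":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    ids = df.iloc[:, 0].astype(str).tolist()
    snp_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=np.int8)
    for r in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            cell = str(raw[r, c]).strip()
            if cell not in ("0", "1", "2", "9"):
                raise ParseError(
                    f"invalid genotype {cell!r} at (row {ids[r]}, column {snp_ids[c]})"
                )
            values[r, c] = int(cell)
    return GenotypeMatrix(ids, values, snp_ids)


def write_genotypes(g: GenotypeMatrix, path, sep: str = "\t") -> None:
    snp_ids = g.snp_ids or [f"snp{i + 1}" for i in range(g.n_snps)]
    with open(path, "w") as fh:
        fh.write(sep.join(["id", *snp_ids]) + "\n")
        for ind, row in zip(g.individual_ids, g.values):
            fh.write(sep.join([ind, *map(str, row.tolist())]) + "\n")


def _read_plink_ped(path) -> GenotypeMatrix:
    """PLINK .ped convenience reader (biallelic; phase in the file is ignored)."""
    ids: list[str] = []
    rows: list[list[int]] = []
    ref_allele: list[str | None] = []
    for lineno, line in enumerate(open(path), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) < 8 or (len(fields) - 6) % 2:
            raise ParseError(f".ped line {lineno}: expected 6 columns + allele pairs")
        ids.append(fields[1])
        alleles = fields[6:]
        n_snp = len(alleles) // 2
        if not ref_allele:
            ref_allele = [None] * n_snp
        if len(ref_allele) != n_snp:
            raise ParseError(f".ped line {lineno}: inconsistent SNP count")
        row = []
        for k in range(n_snp):
            a, b = alleles[2 * k], alleles[2 * k + 1]
            if a == "0" or b == "0":
                row.append(MISSING)
                continue
            if ref_allele[k] is None:
                ref_allele[k] = a
            ref = ref_allele[k]
            alt = {x for x in (a, b) if x != ref}
            if len(alt) > 1:
                raise ParseError(f".ped line {lineno}, SNP {k + 1}: >2 alleles")
            row.append(int(a == ref) + int(b == ref))
        rows.append(row)
    return GenotypeMatrix(ids, np.asarray(rows, dtype=np.int8))


def read_map(path, sep: str | None = None) -> SnpMap:
    """Read a 3-column (snp, chrom, pos) map file; header row auto-detected."""
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python", header=None)
    first = str(df.iloc[0, 2])
    if not first.lstrip("-").isdigit():  # header row
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 3:
        raise ParseError("map file needs 3 columns: snp, chromosome, position")
    return SnpMap.from_frame(df.iloc[:, :3])


def read_plink_map(path) -> SnpMap:
    """PLINK .map (chrom, snp, cM, bp) convenience reader."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str, engine="python", header=None)
    if df.shape[1] < 4:
        raise ParseError(".map file needs 4 columns: chrom, snp, cM, bp")
    return SnpMap.from_frame(df.iloc[:, [1, 0, 3]])


def write_map(m: SnpMap, path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index=False)


def read_pedigree(path, sep: str | None = None) -> PedigreeTable:
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python", header=None)
    if df.shape[1] < 2:
        raise ParseError("pedigree file needs 2 columns: individual, sire")
    low = {str(x).lower() for x in df.iloc[0, :2]}
    if low & {"id", "individual", "individual_id", "animal"}:
        df = df.iloc[1:].reset_index(drop=True)
    return PedigreeTable(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist())


def write_pedigree(p: PedigreeTable, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for ind, sire in zip(p.individual_id, p.sire_id):
            fh.write(f"{ind}{sep}{sire}\n")


def align(
    genotypes: GenotypeMatrix,
    snp_map: SnpMap,
    pedigree: PedigreeTable | None = None,
) -> AlignedBundle:
    """Validate the three inputs against each other.

    Asserts genotype column count equals map length and returns per-chromosome
    column slices.  Pedigree ids absent from the genotypes are flagged (not an
    error: candidate sires may legitimately be un-genotyped).
    """
    if genotypes.n_snps != len(snp_map):
        raise ValidationError(
            f"genotype columns ({genotypes.n_snps}) != map length ({len(snp_map)})"
        )
    flagged: list[str] = []
    if pedigree is not None:
        known = set(genotypes.individual_ids)
        for ind, sire in zip(pedigree.individual_id, pedigree.sire_id):
            if ind not in known:
                flagged.append(ind)
            if sire != UNKNOWN_PARENT and sire not in known:
                flagged.append(sire)
    return AlignedBundle(
        genotypes,
        snp_map,
        pedigree,
        chromosome_slices=snp_map.chromosome_slices(),
        flagged_pedigree_ids=sorted(set(flagged)),
    )
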