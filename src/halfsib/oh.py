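"""Opposing-homozygote (OH) statistics.

An opposing homozygote is a locus where one individual is homozygous for one
allele (genotype 0) and the other individual homozygous for the alternative
(genotype 2).  OH counts are Mendelian-inconsistency evidence: near zero for
true parent-offspring pairs, intermediate for half-sibs, highest for
unrelated pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, UNKNOWN_PARENT, GenotypeMatrix, HalfsibError, PedigreeTable


@dataclass
class OHMatrix:
    """Symmetric individuals x individuals matrix of OH counts."""

    individual_ids: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.individual_ids)
        if self.counts.shape != (n, n):
            raise HalfsibError("OH count matrix shape does not match id list")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def index_of(self, individual_id: str) -> int:
        return self.individual_ids.index(individual_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.individual_ids, columns=self.individual_ids
        )


@dataclass
class OHExpectations:
    """Closed-form expected OH counts under random mating (per-locus p^2 q^2 terms)."""

    e_unrelated: float
    e_halfsib: float
    e_fullsib: float
    cutoff: float


@dataclass
class ParentageResult:
    pedigree: PedigreeTable
    conflicts: dict[str, list[str]] = field(default_factory=dict)
    min_oh: dict[str, int] = field(default_factory=dict)


@dataclass
class SeparationResult:
    """Separation diagnostics over sorted pairwise OH counts."""

    sv: float
    cutoff_count: int
    sorted_pairs: pd.DataFrame  # columns: rank, count, label (true/false/"")


def count_oh(gi, gj) -> int:
    """Number of loci where one row is homozygous 0 and the other homozygous 2.

    Loci with a missing genotype (9) in either row are excluded.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise HalfsibError("genotype rows differ in length")
    return int(np.count_nonzero(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))


def ohg(g: GenotypeMatrix) -> OHMatrix:
    """Pairwise OH count matrix (symmetric, zero diagonal)."""
    if g.n_individuals < 2:
        raise HalfsibError("OH matrix needs at least 2 individuals")
    counts = cross_oh(g.values, g.values)
    np.fill_diagonal(counts, 0)
    return OHMatrix(list(g.individual_ids), counts)


def cross_oh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """OH counts between every row of ``a`` and every row of ``b``."""
    a0 = (np.asarray(a) == 0).astype(np.int64)
    a2 = (np.asarray(a) == 2).astype(np.int64)
    b0 = (np.asarray(b) == 0).astype(np.int64)
    b2 = (np.asarray(b) == 2).astype(np.int64)
    return a0 @ b2.T + a2 @ b0.T


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP reference-allele frequency: mean genotype / 2 over non-missing."""
    v = np.asarray(g.values, dtype=float)
    v[v == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(v, axis=0) / 2.0
    return np.nan_to_num(freq, nan=0.5)


def expected_oh(freqs, cutoff_fraction: float = 0.9) -> OHExpectations:
    """Expected OH counts for unrelated / half-sib / full-sib pairs.

    With q = 1 - p per locus: E[unrelated] = sum 2 p^2 q^2,
    E[half-sib] = sum p^2 q^2, E[full-sib] = sum p^2 q^2 / 2.  The acceptance
    cutoff sits ``cutoff_fraction`` of the way from the half-sib to the
    unrelated expectation.
    """
    p = np.asarray(freqs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise HalfsibError("allele frequencies must lie in [0, 1]")
    term = np.sum(p**2 * (1 - p) ** 2)
    e_un = 2.0 * term
    e_hs = float(term)
    return OHExpectations(
        e_unrelated=float(e_un),
        e_halfsib=e_hs,
        e_fullsib=float(term / 2.0),
        cutoff=float(e_hs + cutoff_fraction * (e_un - e_hs)),
    )


def pogc(
    oh: OHMatrix,
    max_mismatch: int | None = None,
    n_snps: int | None = None,
    candidates: list[str] | None = None,
) -> ParentageResult:
    """Parent-offspring assignment from the OH matrix.

    Each individual is assigned the candidate with minimal OH count, provided
    that count is at most ``max_mismatch`` (default 1% of ``n_snps``).  Ties at
    the minimum leave the individual unassigned and are reported in
    ``conflicts`` rather than broken silently.
    """
    if max_mismatch is None:
        if n_snps is None:
            raise HalfsibError("pogc needs max_mismatch or n_snps for the 1% default")
        max_mismatch = round(0.01 * n_snps)
    if max_mismatch < 0:
        raise HalfsibError("max_mismatch must be >= 0")
    ids = oh.individual_ids
    if candidates is None:
        cand_idx = np.arange(oh.n)
    else:
        cand_idx = np.asarray([oh.index_of(c) for c in candidates])
    sires, conflicts, min_oh = [], {}, {}
    for i, ind in enumerate(ids):
        pool = cand_idx[cand_idx != i]
        if pool.size == 0:
            sires.append(UNKNOWN_PARENT)
            continue
        row = oh.counts[i, pool]
        best = int(row.min())
        min_oh[ind] = best
        if best > max_mismatch:
            sires.append(UNKNOWN_PARENT)
            continue
        winners = [ids[j] for j in pool[row == best]]
        if len(winners) > 1:
            conflicts[ind] = winners
            sires.append(UNKNOWN_PARENT)
        else:
            sires.append(winners[0])
    return ParentageResult(PedigreeTable(list(ids), sires), conflicts, min_oh)


def _midpoint(lo: float, hi: float) -> int:
    return math.floor((lo + hi) / 2.0)


def separation_value(
    oh: OHMatrix, pedigree: PedigreeTable | None = None
) -> SeparationResult:
    """Separation diagnostics for parentage panels.

    With a pedigree: sv = (min OH over false sire-offspring pairs - max OH
    over true pairs) / max OH in the dataset; the cutoff count is the midpoint
    of that gap.  Without a pedigree: the largest gap between consecutive
    sorted upper-triangle values, divided by the maximum.
    """
    iu = np.triu_indices(oh.n, k=1)
    values = oh.counts[iu]
    max_all = int(values.max()) if values.size else 0
    if max_all == 0:
        raise HalfsibError("all pairwise OH counts are zero; separation undefined")

    if pedigree is not None:
        known = set(oh.individual_ids)
        true_pairs = {
            frozenset((i, s)) for i, s in pedigree.known_pairs() if i in known and s in known
        }
        if not true_pairs:
            raise HalfsibError("pedigree contains no genotyped sire-offspring pair")
        labels = np.array(
            [
                "true"
                if frozenset((oh.individual_ids[a], oh.individual_ids[b])) in true_pairs
                else "false"
                for a, b in zip(*iu)
            ]
        )
        max_true = int(values[labels == "true"].max())
        min_false = int(values[labels == "false"].min())
        sv = (min_false - max_true) / max_all
        cutoff = _midpoint(max_true, min_false)
    else:
        labels = np.array([""] * values.size)
        srt = np.sort(values)
        gaps = np.diff(srt)
        k = int(np.argmax(gaps)) if gaps.size else 0
        sv = (int(gaps[k]) if gaps.size else 0) / max_all
        cutoff = _midpoint(int(srt[k]), int(srt[k + 1])) if gaps.size else int(srt[0])

    order = np.argsort(values, kind="stable")
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, values.size + 1),
            "count": values[order],
            "label": labels[order],
        }
    )
    return SeparationResult(sv=float(sv), cutoff_count=int(cutoff), sorted_pairs=frame)
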