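"""Half-sib family reconstruction by recursive hierarchical clustering.

Individuals are recursively bisected with Ward's minimum-variance linkage on
Manhattan distances between rows of the opposing-homozygote matrix; a cluster
becomes a family group once every within-cluster pair passes the chosen
separation criterion.  Because the input to Ward is a Manhattan (not
Euclidean) condensed distance matrix, the agglomeration follows the standard
Lance-Williams recurrence d(k, i+j) = sqrt(((n_i+n_k) d(k,i)^2 +
(n_j+n_k) d(k,j)^2 - n_k d(i,j)^2) / (n_i+n_j+n_k)) applied to those
Manhattan values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import blocks as _blocks
from . import oh as _oh
from .io import GenotypeMatrix, HalfsibError, PedigreeTable, SnpMap, UNKNOWN_PARENT


@dataclass
class FamilyAssignment:
    """Group label per individual; 0 means explicitly unassigned."""

    individual_ids: list[str]
    labels: np.ndarray  # int, >= 0
    flagged: list[list[str]] = field(default_factory=list)  # terminal clusters failing criterion

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for ind, lab in zip(self.individual_ids, self.labels):
            if lab > 0:
                out.setdefault(int(lab), []).append(ind)
        return out

    def partition(self) -> set[frozenset[str]]:
        """Label-free view of the grouping (for comparisons up to renaming)."""
        return {frozenset(v) for v in self.groups().values()}


class ManualCriterion:
    """Fixed maximum OH count allowed within a family."""

    def __init__(self, max_oh: int):
        if max_oh < 0:
            raise HalfsibError("max_oh must be >= 0")
        self.max_oh = int(max_oh)

    def threshold(self, ctx) -> int:
        return self.max_oh


class RegressionCriterion:
    """Threshold as a linear function of panel size.

    No default coefficients ship with the package: the originals were fitted
    to one sheep population and never published, so they must be supplied
    explicitly for the population at hand.
    """

    def __init__(self, intercept: float, slope: float):
        self.intercept = float(intercept)
        self.slope = float(slope)

    def threshold(self, ctx) -> int:
        return regression_threshold(ctx["n_snps"], self.intercept, self.slope)


class CalusCriterion:
    """Expectation-based threshold from population allele frequencies."""

    def __init__(self, freqs=None, cutoff_fraction: float = 0.9):
        self.freqs = None if freqs is None else np.asarray(freqs, dtype=float)
        self.cutoff_fraction = cutoff_fraction

    def threshold(self, ctx) -> float:
        freqs = self.freqs if self.freqs is not None else ctx["freqs"]
        return _oh.expected_oh(freqs, self.cutoff_fraction).cutoff


class RecombinationCriterion:
    """Accept a cluster when every member needs few recombinations to fit in.

    An individual that does not belong to a half-sib group requires an
    implausible number of apparent recombinations to stay Mendelian-consistent
    with it, so blocking the cluster on one reference chromosome and counting
    per-member events separates members from outsiders.
    """

    def __init__(self, chromosome: str | None = None, max_rec: int = 10):
        self.chromosome = chromosome
        self.max_rec = int(max_rec)

    def resolve_chromosome(self, snp_map: SnpMap) -> str:
        if self.chromosome is not None:
            return self.chromosome
        # default: shortest chromosome in bp span (less recombination)
        spans = {}
        for ch, sl in snp_map.chromosome_slices().items():
            pos = snp_map.position_bp[sl]
            spans[ch] = int(pos[-1] - pos[0])
        return min(sorted(spans), key=lambda c: spans[c])


def regression_threshold(n_snps: int, intercept: float, slope: float) -> int:
    """round(intercept + slope * n_snps), floored at 0 with a warning."""
    raw = intercept + slope * n_snps
    thr = int(round(raw))
    if thr < 0:
        warnings.warn(f"regression threshold {thr} negative; clamped to 0")
        return 0
    return thr


def rpoh(
    g: GenotypeMatrix,
    criterion,
    snp_map: SnpMap | None = None,
) -> FamilyAssignment:
    """Reconstruct half-sib family groups without pedigree records.

    Recursive bisection: Ward linkage over Manhattan distances between the
    individuals' OH-matrix rows (restricted to the current cluster), cut into
    two; a cluster is terminal when it satisfies ``criterion`` or has at most
    2 members.  Terminal clusters that fail the criterion are left unassigned
    (label 0) and reported in ``flagged``.  Group labels are consecutive,
    ordered by smallest member id.
    """
    if g.n_individuals < 2:
        raise HalfsibError("pedigree reconstruction needs at least 2 individuals")
    ohm = _oh.ohg(g)
    ctx = {"n_snps": g.n_snps, "freqs": None}
    if isinstance(criterion, CalusCriterion) and criterion.freqs is None:
        ctx["freqs"] = _oh.allele_frequencies(g)

    if isinstance(criterion, RecombinationCriterion):
        if snp_map is None:
            raise HalfsibError("recombination criterion requires a SNP map")
        chrom = criterion.resolve_chromosome(snp_map)
        slices = snp_map.chromosome_slices()
        if chrom not in slices:
            raise HalfsibError(f"chromosome {chrom!r} not in map")
        ref_cols = slices[chrom]

        def ok(members: np.ndarray) -> bool:
            if members.size < 2:
                return True
            b = _blocks.bmh(g.values[members, ref_cols])
            return bool((_blocks.recombinations(b) <= criterion.max_rec).all())

    else:
        thr = criterion.threshold(ctx)

        def ok(members: np.ndarray) -> bool:
            sub = ohm.counts[np.ix_(members, members)]
            return bool(sub.max() <= thr)

    terminal: list[tuple[np.ndarray, bool]] = []

    def recurse(members: np.ndarray) -> None:
        passed = ok(members)
        if passed or members.size <= 2:
            terminal.append((members, passed))
            return
        feats = ohm.counts[np.ix_(members, members)].astype(float)
        d = squareform(_manhattan(feats), checks=False)
        cut = fcluster(linkage(d, method="ward"), 2, criterion="maxclust")
        left = members[cut == 1]
        right = members[cut == 2]
        if left.size == 0 or right.size == 0:  # degenerate tie; cannot split further
            terminal.append((members, False))
            return
        recurse(left)
        recurse(right)

    recurse(np.arange(g.n_individuals))

    labels = np.zeros(g.n_individuals, dtype=np.int64)
    flagged: list[list[str]] = []
    passed_groups = [m for m, p in terminal if p]
    passed_groups.sort(key=lambda m: min(g.individual_ids[i] for i in m))
    for lab, members in enumerate(passed_groups, start=1):
        labels[members] = lab
    for members, p in terminal:
        if not p:
            flagged.append(sorted(g.individual_ids[i] for i in members))
    return FamilyAssignment(list(g.individual_ids), labels, flagged)


def _manhattan(rows: np.ndarray) -> np.ndarray:
    return np.abs(rows[:, None, :] - rows[None, :, :]).sum(axis=2)


def pedigree_naming(
    assignment: FamilyAssignment,
    g_offspring: GenotypeMatrix,
    g_sires: GenotypeMatrix,
) -> tuple[PedigreeTable, dict]:
    """Match inferred family groups to the most likely candidate sires.

    Each group gets the sire minimizing the total OH against its members.  A
    sire claimed by several groups, and ties broken toward the smaller sire
    id, are reported in the returned flags dict (overlapping generations with
    common ancestors degrade this matching).
    """
    if g_sires.n_individuals == 0:
        raise HalfsibError("no candidate sires supplied")
    if g_sires.n_snps != g_offspring.n_snps:
        raise HalfsibError("sire and offspring genotypes are on different panels")
    cross = _oh.cross_oh(g_offspring.values, g_sires.values)
    idx = {ind: i for i, ind in enumerate(g_offspring.individual_ids)}
    sire_ids = list(g_sires.individual_ids)
    group_sire: dict[int, str] = {}
    flags: dict = {"ties": {}, "multiple_claims": {}}
    for lab, members in sorted(assignment.groups().items()):
        rows = [idx[m] for m in members if m in idx]
        totals = cross[rows].sum(axis=0)
        best = totals.min()
        winners = sorted(sire_ids[j] for j in np.flatnonzero(totals == best))
        if len(winners) > 1:
            flags["ties"][lab] = winners
        group_sire[lab] = winners[0]
    claimed: dict[str, list[int]] = {}
    for lab, sire in group_sire.items():
        claimed.setdefault(sire, []).append(lab)
    flags["multiple_claims"] = {s: v for s, v in claimed.items() if len(v) > 1}

    sires = [
        group_sire.get(int(lab), UNKNOWN_PARENT) if lab > 0 else UNKNOWN_PARENT
        for lab in assignment.labels
    ]
    return PedigreeTable(list(assignment.individual_ids), sires), flags
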