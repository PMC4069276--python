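"""Paternal-origin block construction and recombination-event detection.

A half-sib family is partitioned at every informative SNP (one where an
opposing-homozygote pair exists among the sibs, implying a heterozygous sire)
into two groups, one per sire strand.  Scanning SNPs in map order and keeping
group orientation consistent yields, per individual, a run-length "block"
structure of which sire strand was inherited; label switches are
recombination events.  Labels are 1/2 with 0 = undetermined; the global
1 <-> 2 swap is a symmetry of the structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, HalfsibError


@dataclass
class BlockResult:
    """Per-individual, per-SNP sire-strand labels plus scan diagnostics.

    ``genotyping_errors`` lists (individual index, snp index) positions where
    an isolated single-SNP contradiction was suppressed rather than treated
    as a double recombination.
    """

    individual_ids: list[str]
    labels: np.ndarray  # n x n_snps int8 in {0,1,2}
    genotyping_errors: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return self.labels.shape[1]


@dataclass
class RecombinationProfile:
    """Per-interval recombination totals across one or more families."""

    events: np.ndarray  # total events per interval
    meioses: np.ndarray  # informative meioses per interval
    rate: np.ndarray  # events / meioses (0 where no meioses)
    family_events: list[np.ndarray] = field(default_factory=list)
    family_meioses: list[np.ndarray] = field(default_factory=list)


def _family_values(g) -> tuple[list[str], np.ndarray]:
    if isinstance(g, GenotypeMatrix):
        return list(g.individual_ids), g.values
    v = np.asarray(g, dtype=np.int8)
    return [str(i) for i in range(v.shape[0])], v


def bmh(g_family, persist_window: int = 1) -> BlockResult:
    """Build the paternal-origin block structure for one chromosome.

    The input must already be a single-chromosome slice in map order.  The
    scan anchors at the first informative SNP (homozygote-0 carriers form
    group 1, homozygote-2 carriers group 2).  At each later informative SNP
    the two homozygote classes are oriented onto groups {1,2} so as to
    minimise the number of already-labelled individuals that would switch
    (ties keep the previous orientation).  A labelled individual whose
    homozygote class contradicts its group switches only if the contradiction
    persists for ``persist_window`` further informative observations of that
    individual; an isolated contradiction flanked by the original group is
    recorded as a genotyping error and ignored.
    """
    ids, v = _family_values(g_family)
    n, m = v.shape
    if n < 2:
        raise HalfsibError("block construction needs at least 2 individuals")

    hom0 = v == 0
    hom2 = v == 2
    informative = np.flatnonzero(hom0.any(axis=0) & hom2.any(axis=0))

    labels = np.zeros((n, m), dtype=np.int8)
    result = BlockResult(ids, labels)
    if informative.size == 0:
        warnings.warn("no opposing-homozygous SNP on chromosome; labels all 0")
        return result

    cur = np.zeros(n, dtype=np.int8)  # committed group per individual
    # change events per individual: list of (snp index, label)
    events: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    # pending candidate switch: individual -> [start snp, new label, confirmations]
    pending: dict[int, list[int]] = {}
    orient = (1, 2)  # (group of hom0 carriers, group of hom2 carriers)

    for j, k in enumerate(informative):
        c0 = np.flatnonzero(hom0[:, k])
        c2 = np.flatnonzero(hom2[:, k])
        if j == 0:
            orient = (1, 2)
        else:
            cost_keep = _switch_cost(cur, c0, c2, orient)
            flipped = (orient[1], orient[0])
            cost_flip = _switch_cost(cur, c0, c2, flipped)
            if cost_flip < cost_keep:
                orient = flipped
        for members, grp in ((c0, orient[0]), (c2, orient[1])):
            for i in members:
                _observe(i, int(k), int(grp), cur, events, pending, persist_window, result)

    # unresolved pending switches at chromosome end: commit (nothing refuted them)
    for i, (start, new, _conf) in sorted(pending.items()):
        events[i].append((start, new))

    for i in range(n):
        for start, lab in events[i]:
            labels[i, start:] = lab
    return result


def _switch_cost(cur, c0, c2, orient) -> int:
    cost = 0
    for members, grp in ((c0, orient[0]), (c2, orient[1])):
        lab = cur[members]
        cost += int(np.count_nonzero((lab != 0) & (lab != grp)))
    return cost


def _observe(i, k, grp, cur, events, pending, persist_window, result) -> None:
    """Process one homozygous observation of individual ``i`` at SNP ``k``."""
    if cur[i] == 0:
        cur[i] = grp
        events[i].append((k, grp))
        return
    if i in pending:
        start, new, conf = pending[i]
        if grp == new:
            conf += 1
            if conf >= persist_window:
                events[i].append((start, new))
                cur[i] = new
                del pending[i]
                return
            pending[i] = [start, new, conf]
            return
        # returned to the original group: isolated contradiction => genotyping error
        result.genotyping_errors.append((i, start))
        del pending[i]
        return
    if grp != cur[i]:
        if persist_window <= 0:
            events[i].append((k, grp))
            cur[i] = grp
        else:
            pending[i] = [k, grp, 0]


def pm(b: BlockResult | np.ndarray) -> np.ndarray:
    """Recombination-event matrix: n x (n_snps - 1) in {0,1}.

    An event at interval k marks a label change between individual i's
    nearest determined SNPs bracketing that interval; a switch across a run
    of undetermined labels is assigned to the interval following the last
    determined SNP before the gap.
    """
    labels = b.labels if isinstance(b, BlockResult) else np.asarray(b)
    n, m = labels.shape
    out = np.zeros((n, m - 1), dtype=np.int8)
    for i in range(n):
        det = np.flatnonzero(labels[i])
        if det.size < 2:
            continue
        lab = labels[i, det]
        change = np.flatnonzero(np.diff(lab) != 0)
        out[i, det[change]] = 1
    return out


def recombinations(b: BlockResult | np.ndarray) -> np.ndarray:
    """Recombination count per individual (row sums of :func:`pm`)."""
    return pm(b).sum(axis=1).astype(np.int64)


def hbp(offspring_haplotypes, sire_haplotypes) -> np.ndarray:
    """Label each offspring haplotype by the sire strand it matches.

    Inputs are allele matrices in {0,1,9} (2 x n_snps each).  Per SNP a
    haplotype gets label 1/2 where exactly one sire strand matches, 0 where
    both or neither match or any allele is missing.
    """
    off = np.asarray(offspring_haplotypes)
    sire = np.asarray(sire_haplotypes.alleles if hasattr(sire_haplotypes, "alleles") else sire_haplotypes)
    if off.shape[1] != sire.shape[1]:
        raise HalfsibError("offspring/sire haplotype length mismatch")
    out = np.zeros(off.shape, dtype=np.int8)
    callable_ = (off != 9) & (sire[0] != 9)[None, :] & (sire[1] != 9)[None, :]
    m1 = off == sire[0][None, :]
    m2 = off == sire[1][None, :]
    out[callable_ & m1 & ~m2] = 1
    out[callable_ & m2 & ~m1] = 2
    return out


def recombination_profile(blocks: list) -> RecombinationProfile:
    """Aggregate per-interval event counts and rates across families.

    A meiosis is informative at interval k if the individual has a determined
    label on both sides of the interval.
    """
    if not blocks:
        raise HalfsibError("no block matrices supplied")
    mats = [b.labels if isinstance(b, BlockResult) else np.asarray(b) for b in blocks]
    n_int = mats[0].shape[1] - 1
    if any(x.shape[1] - 1 != n_int for x in mats):
        raise HalfsibError("block matrices are on different map slices")
    fam_events, fam_meioses = [], []
    for labels in mats:
        ev = pm(labels).sum(axis=0).astype(np.int64)
        det = labels != 0
        left = np.maximum.accumulate(det, axis=1)[:, :-1]
        right = np.maximum.accumulate(det[:, ::-1], axis=1)[:, ::-1][:, 1:]
        fam_events.append(ev)
        fam_meioses.append((left & right).sum(axis=0).astype(np.int64))
    events = np.sum(fam_events, axis=0)
    meioses = np.sum(fam_meioses, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(meioses > 0, events / np.maximum(meioses, 1), 0.0)
    return RecombinationProfile(events, meioses, rate, fam_events, fam_meioses)


def flag_map_errors(
    profile: RecombinationProfile,
    min_families: int = 3,
    rate_factor: float = 5.0,
    min_events: int = 2,
    window: int = 5,
) -> list[int]:
    """SNP indices showing excessive recombination consistently across families.

    A displaced SNP (or segment) forces apparent block breaks in every family
    it is informative for, but the exact commit interval jitters from sib to
    sib, so evidence is collected regionally: a family votes for SNP s when
    the events it contributes within ``window`` intervals of s number at
    least ``min_events`` (a real crossover contributes one) and exceed
    ``rate_factor`` times the family's expected count for a span that size
    (baseline = the family's median interval rate, falling back to its mean
    since the median is usually 0 at realistic crossover counts).  A SNP is
    flagged when at least ``min_families`` families vote for it
    independently.
    """
    n_fam = len(profile.family_events)
    if n_fam < min_families:
        return []
    n_int = len(profile.events)
    votes = np.zeros(n_int + 1, dtype=np.int64)  # per SNP
    kernel = np.ones(2 * window + 1)
    for ev, mei in zip(profile.family_events, profile.family_meioses):
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(mei > 0, ev / np.maximum(mei, 1), 0.0)
        informative = mei > 0
        if not informative.any():
            continue
        base = float(np.median(rate[informative]))
        if base == 0.0:
            base = float(np.mean(rate[informative]))
        if base == 0.0:
            continue
        mean_meioses = float(mei[informative].mean())
        # family's events in the +/-window interval neighbourhood of each SNP
        snp_ev = np.convolve(np.r_[ev, 0.0], kernel, mode="same")
        expected = rate_factor * base * mean_meioses * (2 * window + 1)
        votes += (snp_ev >= max(min_events, expected)).astype(np.int64)
    return np.flatnonzero(votes >= min_families).tolist()
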