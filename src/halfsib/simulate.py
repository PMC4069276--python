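"""Gamete-dropping simulator for half-sib families with known truth.

One generation: each family has one sire with two random founder strands and
one unrelated dam per offspring.  Paternal gametes recombine with a Poisson
(no-interference) crossover count per chromosome; truth (sire strands,
per-offspring transmission vectors, crossover intervals, dam alleles) is
retained so every downstream inference can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, HalfsibError, PedigreeTable, SnpMap


@dataclass
class SimConfig:
    n_families: int = 1
    family_sizes: int | list[int] = 8
    n_snps: int = 2000  # per chromosome
    n_chromosomes: int = 1
    chromosome_length_morgans: float = 1.0
    freq_low: float = 0.1
    freq_high: float = 0.9
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    fixed_crossovers: int | None = None  # deterministic mode for tests
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.family_sizes, int):
            return [self.family_sizes] * self.n_families
        if len(self.family_sizes) != self.n_families:
            raise HalfsibError("family_sizes length != n_families")
        return list(self.family_sizes)

    def validate(self) -> None:
        for name in ("genotyping_error_rate", "missing_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise HalfsibError(f"{name} must lie in [0, 1]")
        if self.n_snps < 2:
            raise HalfsibError("need at least 2 SNPs per chromosome")
        if self.chromosome_length_morgans < 0:
            raise HalfsibError("chromosome length must be >= 0")
        if not 0.0 <= self.freq_low <= self.freq_high <= 1.0:
            raise HalfsibError("frequency bounds must satisfy 0 <= low <= high <= 1")


@dataclass
class FamilyTruth:
    sire_id: str
    offspring_ids: list[str]
    sire_haplotypes: np.ndarray  # 2 x M alleles {0,1}
    transmission: np.ndarray  # n x M strand index {0,1}
    crossover_intervals: list[list[int]]  # per offspring, global interval indices
    dam_alleles: np.ndarray  # n x M {0,1}
    clean_genotypes: np.ndarray  # n x M before error/missing masking


@dataclass
class SimTruth:
    families: list[FamilyTruth] = field(default_factory=list)
    freqs: np.ndarray | None = None

    def family_of(self, sire_id: str) -> FamilyTruth:
        for f in self.families:
            if f.sire_id == sire_id:
                return f
        raise KeyError(sire_id)


@dataclass
class SimResult:
    genotypes: GenotypeMatrix  # offspring only
    sire_genotypes: GenotypeMatrix
    snp_map: SnpMap
    pedigree: PedigreeTable
    truth: SimTruth


def _drop_gamete(strands: np.ndarray, boundaries, rng, length_m, fixed=None):
    """One meiosis over concatenated chromosomes; returns (allele, strand, xovers)."""
    total = strands.shape[1]
    trans = np.empty(total, dtype=np.int8)
    xovers: list[int] = []
    for lo, hi in boundaries:
        m = hi - lo
        start = rng.integers(0, 2)
        n_x = fixed if fixed is not None else rng.poisson(length_m)
        ivals = np.sort(rng.integers(0, m - 1, size=n_x)) if n_x else np.empty(0, int)
        flips = np.zeros(m, dtype=np.int64)
        for k in ivals:
            flips[k + 1 :] += 1
        trans[lo:hi] = (start + flips) % 2
        # crossovers cancelling in pairs within one interval leave no switch
        seen = np.flatnonzero(np.diff((start + flips) % 2) != 0)
        xovers.extend((lo + int(k)) for k in seen)
    allele = strands[trans, np.arange(total)]
    return allele.astype(np.int8), trans, xovers


def simulate_population(cfg: SimConfig) -> SimResult:
    """Generate genotypes, map, pedigree and full truth for half-sib families."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_chrom, m = cfg.n_chromosomes, cfg.n_snps
    total = n_chrom * m
    boundaries = [(c * m, (c + 1) * m) for c in range(n_chrom)]

    freqs = rng.uniform(cfg.freq_low, cfg.freq_high, size=total)
    snp_ids = [f"snp{c + 1}_{k + 1}" for c in range(n_chrom) for k in range(m)]
    chroms = [str(c + 1) for c in range(n_chrom) for _ in range(m)]
    positions = [1 + 1000 * k for _ in range(n_chrom) for k in range(m)]
    snp_map = SnpMap.from_frame(
        pd.DataFrame({"snp": snp_ids, "chrom": chroms, "pos": positions})
    )

    truth = SimTruth(freqs=freqs)
    off_ids: list[str] = []
    off_rows: list[np.ndarray] = []
    ped_ind: list[str] = []
    ped_sire: list[str] = []
    sire_ids: list[str] = []
    sire_rows: list[np.ndarray] = []

    for f, size in enumerate(cfg.sizes(), start=1):
        sire_id = f"S{f}"
        strands = (rng.random((2, total)) < freqs).astype(np.int8)
        sire_ids.append(sire_id)
        sire_rows.append(strands.sum(axis=0).astype(np.int8))
        trans = np.empty((size, total), dtype=np.int8)
        dam = (rng.random((size, total)) < freqs).astype(np.int8)
        xo: list[list[int]] = []
        kids = [f"S{f}_O{o + 1}" for o in range(size)]
        geno = np.empty((size, total), dtype=np.int8)
        for o in range(size):
            allele, tv, xv = _drop_gamete(
                strands, boundaries, rng, cfg.chromosome_length_morgans, cfg.fixed_crossovers
            )
            trans[o] = tv
            xo.append(xv)
            geno[o] = allele + dam[o]
        truth.families.append(
            FamilyTruth(sire_id, kids, strands, trans, xo, dam, geno.copy())
        )
        off_ids.extend(kids)
        off_rows.append(geno)
        ped_ind.extend(kids)
        ped_sire.extend([sire_id] * size)

    values = np.vstack(off_rows)
    values = _mask(values, cfg, rng)
    return SimResult(
        genotypes=GenotypeMatrix(off_ids, values, snp_ids),
        sire_genotypes=GenotypeMatrix(sire_ids, np.vstack(sire_rows), snp_ids),
        snp_map=snp_map,
        pedigree=PedigreeTable(ped_ind, ped_sire),
        truth=truth,
    )


def _mask(values: np.ndarray, cfg: SimConfig, rng) -> np.ndarray:
    out = values.copy()
    if cfg.genotyping_error_rate > 0:
        hit = rng.random(out.shape) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=out.shape)  # uniformly different genotype
        out[hit] = (out[hit] + shift[hit]) % 3
    if cfg.missing_rate > 0:
        out[rng.random(out.shape) < cfg.missing_rate] = 9
    return out


# ---------------------------------------------------------------------------
# pair generators for OH-expectation Monte Carlo
# ---------------------------------------------------------------------------


def simulate_unrelated_pairs(freqs, n_pairs: int, rng) -> np.ndarray:
    """OH count per pair of independent Hardy-Weinberg individuals."""
    p = np.asarray(freqs, dtype=float)
    g1 = _hw_genotypes(p, n_pairs, rng)
    g2 = _hw_genotypes(p, n_pairs, rng)
    return _pair_oh(g1, g2)


def simulate_halfsib_pairs(freqs, n_pairs: int, rng) -> np.ndarray:
    """OH count per pair of offspring sharing a sire, dams unrelated."""
    p = np.asarray(freqs, dtype=float)
    sire = (rng.random((n_pairs, 2, p.size)) < p).astype(np.int8)
    g1 = _gamete(sire, rng) + _bern(p, n_pairs, rng)
    g2 = _gamete(sire, rng) + _bern(p, n_pairs, rng)
    return _pair_oh(g1, g2)


def simulate_fullsib_pairs(freqs, n_pairs: int, rng) -> np.ndarray:
    """OH count per pair of offspring sharing sire and dam."""
    p = np.asarray(freqs, dtype=float)
    sire = (rng.random((n_pairs, 2, p.size)) < p).astype(np.int8)
    dam = (rng.random((n_pairs, 2, p.size)) < p).astype(np.int8)
    g1 = _gamete(sire, rng) + _gamete(dam, rng)
    g2 = _gamete(sire, rng) + _gamete(dam, rng)
    return _pair_oh(g1, g2)


def _hw_genotypes(p, n, rng) -> np.ndarray:
    return (_bern(p, n, rng) + _bern(p, n, rng)).astype(np.int8)


def _bern(p, n, rng) -> np.ndarray:
    return (rng.random((n, p.size)) < p).astype(np.int8)


def _gamete(parents, rng) -> np.ndarray:
    n, _, m = parents.shape
    pick = rng.integers(0, 2, size=(n, m))
    return np.take_along_axis(parents, pick[:, None, :], axis=1)[:, 0, :]


def _pair_oh(g1, g2) -> np.ndarray:
    return (((g1 == 0) & (g2 == 2)) | ((g1 == 2) & (g2 == 0))).sum(axis=1)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoreReport:
    block_r2: float
    accuracy: float
    call_rate: float
    crossover_count_error: float
    orientation_swapped: bool


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0:
        return float("nan")
    if a.std() == 0.0 or b.std() == 0.0:
        return 1.0 if (a == b).all() else 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def score_blocks(labels: np.ndarray, fam: FamilyTruth) -> ScoreReport:
    """Score inferred block labels against the true transmission vectors.

    The global 1<->2 label swap is resolved toward the better orientation;
    metrics are over determined loci only.
    """
    labels = labels.labels if hasattr(labels, "labels") else np.asarray(labels)
    det = labels != 0
    truth = fam.transmission  # 0/1 strand index
    best = None
    for swap in (False, True):
        inf = (labels - 1) if not swap else (2 - labels)  # -> 0/1 over determined
        acc = float((inf[det] == truth[det]).mean()) if det.any() else float("nan")
        if best is None or acc > best[1]:
            best = (swap, acc, inf)
    swap, acc, inf = best
    r2 = _r2(inf[det].astype(float), truth[det].astype(float))
    from . import blocks as _blocks

    inferred_counts = _blocks.recombinations(labels)
    true_counts = np.array([len(x) for x in fam.crossover_intervals])
    return ScoreReport(
        block_r2=r2,
        accuracy=acc,
        call_rate=float(det.mean()),
        crossover_count_error=float(np.abs(inferred_counts - true_counts).mean()),
        orientation_swapped=swap,
    )


def score_alleles(called: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, call_rate, r2) of called alleles (9 = uncalled) vs truth."""
    called = np.asarray(called)
    truth = np.asarray(truth)
    mask = called != 9
    if not mask.any():
        return float("nan"), 0.0, float("nan")
    acc = float((called[mask] == truth[mask]).mean())
    r2 = _r2(called[mask].astype(float), truth[mask].astype(float))
    return acc, float(mask.mean()), r2


def score_sire(sire, fam: FamilyTruth) -> tuple[float, float]:
    """(accuracy, call_rate) of inferred sire strands, best orientation."""
    alleles = sire.alleles if hasattr(sire, "alleles") else np.asarray(sire)
    best = (0.0, 0.0)
    for cand in (alleles, alleles[::-1]):
        mask = cand != 9
        if not mask.any():
            continue
        acc = float((cand[mask] == fam.sire_haplotypes[mask]).mean())
        if acc > best[0]:
            best = (acc, float(mask.mean()))
    return best
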