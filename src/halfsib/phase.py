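"""Sire-haplotype inference, offspring phasing and paternal imputation.

The sire is typically un-genotyped: its two strands are inferred by averaging
offspring genotypes within each block group (``ssp``), offspring paternal
haplotypes are read off the block structure against those strands (``phf``)
and the maternal haplotype is the genotype minus the paternal one.  ``impute``
lifts a low-density block structure onto a high-density sire scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import blocks as _blocks
from .io import GenotypeMatrix, HalfsibError, SnpMap

UNCALLED = 9


@dataclass
class SireHaplotypes:
    """Two sire strands as allele rows in {0,1,9}; row g pairs with block group g+1."""

    alleles: np.ndarray  # 2 x n_snps int8

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != 2:
            raise HalfsibError("sire haplotypes must be a 2 x n_snps matrix")

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def swapped(self) -> "SireHaplotypes":
        return SireHaplotypes(self.alleles[::-1].copy())


@dataclass
class PhasedFamily:
    """Offspring paternal/maternal allele matrices in {0,1,9}."""

    individual_ids: list[str]
    paternal: np.ndarray
    maternal: np.ndarray
    conflicts: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class ChromosomePhasing:
    blocks: _blocks.BlockResult
    sire: SireHaplotypes
    phased: PhasedFamily


def ssp(
    b: _blocks.BlockResult | np.ndarray,
    g_family,
    lower: float = 0.5,
    upper: float = 1.5,
) -> SireHaplotypes:
    """Infer sire strands by averaging genotypes within each block group.

    For strand s and SNP k the mean genotype of individuals labelled s at k
    (missing genotypes excluded) is taken: mean < ``lower`` calls allele 0,
    mean > ``upper`` calls allele 1, anything in between (including an empty
    group) is left uncalled — a group mean near 1 cannot separate the
    paternal from the average maternal contribution.
    """
    labels = b.labels if isinstance(b, _blocks.BlockResult) else np.asarray(b)
    _, v = _blocks._family_values(g_family)
    if labels.shape != v.shape:
        raise HalfsibError("block matrix and genotypes are not aligned")
    out = np.full((2, v.shape[1]), UNCALLED, dtype=np.int8)
    gf = v.astype(float)
    gf[v == 9] = np.nan
    for s in (1, 2):
        member = labels == s
        with np.errstate(invalid="ignore"):
            sums = np.nansum(np.where(member, gf, np.nan), axis=0)
            counts = (member & ~np.isnan(gf)).sum(axis=0)
        mean = np.divide(sums, counts, out=np.full(v.shape[1], np.nan), where=counts > 0)
        out[s - 1, mean < lower] = 0
        out[s - 1, mean > upper] = 1
    return SireHaplotypes(out)


def phf(
    g_family,
    b: _blocks.BlockResult | np.ndarray,
    sire: SireHaplotypes,
) -> PhasedFamily:
    """Phase offspring against the sire strands selected by their block labels.

    paternal(i,k) is the allele of sire strand b(i,k); an offspring homozygote
    contradicting that allele voids the call (logged in ``conflicts``) rather
    than overriding the block.  maternal = genotype - paternal where both are
    defined.
    """
    ids, v = _blocks._family_values(g_family)
    labels = b.labels if isinstance(b, _blocks.BlockResult) else np.asarray(b)
    if labels.shape != v.shape:
        raise HalfsibError("block matrix and genotypes are not aligned")
    n, m = v.shape
    paternal = np.full((n, m), UNCALLED, dtype=np.int8)
    for s in (1, 2):
        mask = labels == s
        paternal[mask] = np.broadcast_to(sire.alleles[s - 1], (n, m))[mask]

    # homozygous offspring genotype fixes both alleles; a clash voids the call
    clash = (
        ((v == 0) & (paternal == 1)) | ((v == 2) & (paternal == 0))
    )
    conflicts = [(int(r), int(c)) for r, c in np.argwhere(clash)]
    paternal[clash] = UNCALLED

    maternal = np.full((n, m), UNCALLED, dtype=np.int8)
    ok = (paternal != UNCALLED) & (v != 9)
    maternal[ok] = (v[ok] - paternal[ok]).astype(np.int8)
    bad = ok & ~np.isin(maternal, (0, 1))
    if bad.any():  # heterozygote-against-missing-strand edge; void instead of propagate
        maternal[bad] = UNCALLED
    return PhasedFamily(ids, paternal, maternal, conflicts)


def impute(
    g_low,
    sire_hd: SireHaplotypes,
    ld_index,
    persist_window: int = 1,
) -> np.ndarray:
    """Impute offspring paternal strands from a low-density panel to high density.

    ``g_low`` holds the family's genotypes at the low-density (LD) SNPs, which
    must be a subset of the high-density (HD) panel in identical order;
    ``ld_index`` gives each LD SNP's column in the HD panel.  Blocks are built
    on the LD panel, labels are expanded to HD coordinates (spans between
    determined LD SNPs with equal labels take that label; spans bracketing a
    recombination stay undetermined; edge labels extend outward to the
    chromosome ends) and the sire's HD strands fill in the alleles.

    Because the LD block orientation is arbitrary, the global 1<->2 swap
    against the supplied sire strands is resolved first by minimizing
    offspring-homozygote clashes at the LD positions; at those positions a
    directly-phased allele (offspring homozygote) then takes precedence over
    the scaffold.
    """
    ids, v = _blocks._family_values(g_low)
    ld_index = np.asarray(ld_index, dtype=np.int64)
    n_hd = sire_hd.n_snps
    if ld_index.size != v.shape[1]:
        raise HalfsibError("ld_index length does not match low-density SNP count")
    if (np.diff(ld_index) <= 0).any() or ld_index[0] < 0 or ld_index[-1] >= n_hd:
        raise HalfsibError("LD SNPs must be an ordered subset of the HD panel")

    b = _blocks.bmh(v, persist_window=persist_window)
    n = v.shape[0]

    # resolve the global label swap against the sire strands
    sire_ld = sire_hd.alleles[:, ld_index]
    clashes = []
    for orient in ((0, 1), (1, 0)):
        pat_ld = np.full(v.shape, UNCALLED, dtype=np.int8)
        for s in (1, 2):
            mask = b.labels == s
            pat_ld[mask] = np.broadcast_to(sire_ld[orient[s - 1]], v.shape)[mask]
        clashes.append(
            int((((v == 0) & (pat_ld == 1)) | ((v == 2) & (pat_ld == 0))).sum())
        )
    if clashes[1] < clashes[0]:
        sire_hd = sire_hd.swapped()

    hd_labels = np.zeros((n, n_hd), dtype=np.int8)
    for i in range(n):
        det = np.flatnonzero(b.labels[i])
        if det.size == 0:
            continue
        lab = b.labels[i, det]
        pos = ld_index[det]
        for a in range(det.size - 1):
            if lab[a] == lab[a + 1]:
                hd_labels[i, pos[a] : pos[a + 1] + 1] = lab[a]
            else:  # recombination interval: only the anchors themselves are known
                hd_labels[i, pos[a]] = lab[a]
                hd_labels[i, pos[a + 1]] = lab[a + 1]
        hd_labels[i, : pos[0] + 1] = lab[0]
        hd_labels[i, pos[-1] :] = lab[-1]

    paternal = np.full((n, n_hd), UNCALLED, dtype=np.int8)
    for s in (1, 2):
        mask = hd_labels == s
        paternal[mask] = np.broadcast_to(sire_hd.alleles[s - 1], (n, n_hd))[mask]

    # directly-phased LD positions take precedence over the scaffold
    hom = np.isin(v, (0, 2))
    sub = paternal[:, ld_index]
    sub[hom] = (v[hom] // 2).astype(np.int8)
    paternal[:, ld_index] = sub
    return paternal


def aio(g_family: GenotypeMatrix, snp_map: SnpMap) -> dict[str, ChromosomePhasing]:
    """Run bmh -> ssp -> phf independently per chromosome.

    Chromosomes share no state, so results are identical regardless of
    execution order or worker count.
    """
    if g_family.n_snps != len(snp_map):
        raise HalfsibError("genotypes and map have different SNP counts")
    out: dict[str, ChromosomePhasing] = {}
    for chrom, sl in snp_map.chromosome_slices().items():
        gv = g_family.values[:, sl]
        b = _blocks.bmh(GenotypeMatrix(g_family.individual_ids, gv))
        sire = ssp(b, gv)
        phased = phf(gv, b, sire)
        out[chrom] = ChromosomePhasing(b, sire, phased)
    return out
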