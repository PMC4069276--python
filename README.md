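# halfsib

A toolkit for half-sib family groups genotyped on SNP arrays: opposing-homozygote
(OH) statistics, pedigree reconstruction and parentage assignment, paternal-origin
block structures with recombination-event detection, inference (phasing) of an
un-genotyped sire, phasing of the offspring, and imputation of offspring paternal
haplotypes from low- to high-density panels. A gamete-dropping simulator with full
truth tracking makes every stage testable without external data.

## Key ideas

- An **opposing homozygote** (one individual homozygous 0, the other homozygous 2
  at a locus) is impossible between a true parent and offspring barring genotyping
  error, occurs at an intermediate rate between half-sibs and at roughly twice that
  rate between unrelated pairs. Pairwise OH counts therefore drive parentage
  assignment (`oh.pogc`), separation diagnostics (`oh.separation_value`) and family
  reconstruction by recursive Ward clustering (`pedigree.rpoh`, four separation
  criteria: manual / regression / frequency-expectation / recombination-count).
- An OH locus within a family implies a heterozygous sire; partitioning sibs by
  their homozygote class at such loci, scanning SNPs in map order while minimizing
  group switches, yields per-sib **block structures** of sire-strand inheritance
  (`blocks.bmh`). Label switches are recombination events (`blocks.pm`,
  `blocks.recombinations`); isolated single-SNP contradictions are logged as
  genotyping errors. Excessive, family-consistent recombination flags map errors
  (`blocks.flag_map_errors`).
- Averaging genotypes within block groups calls the **sire haplotypes**
  (`phase.ssp`); overlaying blocks on the sire strands phases the offspring, with
  maternal = genotype − paternal (`phase.phf`); blocks built on a low-density
  panel expanded against a high-density sire scaffold impute the offspring
  paternal strand (`phase.impute`).

## CLI

Every subcommand writes its tables as TSV, a `run.log` of key=value lines
(parameters, seed, all warnings), and a PNG twin for each plotted table.

```bash
halfsib simulate --families 3 --size 8 --snps 2000 --seed 1 --out sim/
halfsib oh matrix      --genotypes sim/genotypes.tsv --out out/
halfsib oh parentage   --genotypes sim/genotypes.tsv --out out/
halfsib oh separation  --genotypes sim/genotypes.tsv --pedigree sim/pedigree.tsv --out out/
halfsib pedigree reconstruct --genotypes sim/genotypes.tsv --method manual --max-oh 100 --out out/
halfsib pedigree name  --genotypes sim/genotypes.tsv --sires sim/sires.tsv \
                       --groups out/groups.tsv --out out/
halfsib blocks build          --genotypes sim/genotypes.tsv --map sim/map.tsv \
                              --pedigree sim/pedigree.tsv --out out/
halfsib blocks recombinations --genotypes sim/genotypes.tsv --map sim/map.tsv \
                              --pedigree sim/pedigree.tsv --out out/
halfsib blocks map-check      --genotypes sim/genotypes.tsv --map sim/map.tsv \
                              --pedigree sim/pedigree.tsv --out out/
halfsib phase family   --genotypes sim/genotypes.tsv --map sim/map.tsv \
                       --pedigree sim/pedigree.tsv --out out/
halfsib impute paternal --ld-genotypes ld.tsv --ld-map ld_map.tsv \
                        --hd-map sim/map.tsv --sire-haplotypes out/sire_S1.tsv --out out/
```

Input formats: genotype matrix (TSV/CSV, header of SNP ids, first column the
individual id, cells 0/1/2 with 9 = missing), 3-column SNP map (name,
chromosome, bp position), 2-column pedigree (individual, sire; `0` = unknown).
PLINK `.ped`/`.map` are supported as convenience readers
(`halfsib.read_genotypes(path, dialect="plink_ped")`).

## Library example

```python
import numpy as np
import halfsib as hs

res = hs.simulate_population(hs.SimConfig(n_families=1, family_sizes=8,
                                          n_snps=2000, seed=1))
blocks = hs.bmh(res.genotypes.values)          # sire-strand labels per sib/SNP
sire = hs.ssp(blocks, res.genotypes.values)    # inferred sire haplotypes
phased = hs.phf(res.genotypes.values, blocks, sire)
ld = np.arange(0, 2000, 10)
imputed = hs.impute(res.genotypes.values[:, ld], sire, ld)
print(hs.score_blocks(blocks, res.truth.families[0]))
```
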