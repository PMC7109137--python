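# gblupkit

Genome-assisted parental selection analysis for two-generation breeding
populations, built as a reusable, tested pipeline:

* **io_formats** — pedigree / phenotype / genotype containers and readers
  (CSV, VCF via cyvcf2, a dosage-TSV dialect), SNP site filters
  (missingness, MAF, 1-bp adjacency and site/taxa coverage filters),
  per-site mean imputation and per-individual heterozygosity.
* **relmat** — pedigree additive relationship matrix (tabular method,
  inbreeding coefficients) and the VanRaden method-1 genomic relationship
  matrix, plus positive-definiteness repair for mixed-model use.
* **mixed_model** — AI-REML (with EM fallback) for the individual-tree
  repeatability model `y = Xb + Za + Zp + e` and the genomic model
  `y = μ1 + Zg + ε`; BLUPs for all individuals in the relationship matrix,
  heritability and repeatability from variance components.
* **pipeline** — own-phenotype BLUP breeding values (BLUP-BV), progeny-based
  general combining ability (GCA), their product-moment correlation, and
  replicated k-fold cross-validated genomic prediction (GEBV accuracy =
  corr(GEBV, BLUP-BV) per validation fold); `run_study` orchestrates the
  whole analysis from a YAML config.
* **simulate** — synthetic breeding populations with known truth: HWE
  founders, random crossing designs, gene-dropped progeny genotypes
  (Poisson crossovers, Haldane), multi-trait phenotypes with additive QTL,
  permanent-environment and year effects. Optionally an *unrecorded* base
  generation gives the accession panel realistic genomic family structure
  while its recorded pedigree shows unknown parents.

## CLI

```sh
gblupkit simulate --seed 1 --out-dir data/            # synthetic study
gblupkit filter data/genotypes.vcf --out filtered.tsv --report report.json
gblupkit relmat --pedigree data/pedigree.csv --out A.csv
gblupkit relmat --genotypes data/genotypes.vcf --out G.csv
gblupkit fit --phenotypes data/phenotypes.csv --pedigree data/pedigree.csv \
             --trait AVFW --out ebv.csv
gblupkit gca --phenotypes data/phenotypes.csv --pedigree data/pedigree.csv \
             --trait AVFW --out gca.csv
gblupkit cv  --blupbv ebv.csv --grm G.csv --folds 11 --repeats 20 --out cv.csv
gblupkit run --config config.yaml --out-dir results/  # full study
```

A `run` config looks like:

```yaml
seed: 1
simulation: {n_founders: 274, n_snps: 6400, progeny_per_cross: 18}
# or instead of `simulation:`:
# inputs: {pedigree: ped.csv, phenotypes: phen.csv, genotypes: g.vcf,
#          genotype_format: vcf}
traits: [AVFW, FIRM]        # default: all traits present
cv: {folds: 11, repeats: 20}
filters: {max_missing_frac: 0.10, min_maf: 0.05, remove_adjacent: true}
```

Outputs: `trait_summary.csv` (per-trait heritability, corr(BLUP-BV, GCA),
mean CV accuracy, mean corr(GEBV, GCA)), per-trait `cv_<trait>.csv` fold
records, `report.txt`, `settings.json`. Identical config + seed reruns are
byte-identical.

## File formats

* **Pedigree CSV** — header `individual,sire,dam`; unknown parents empty or
  `0`; any order (sorted parents-first on read).
* **Phenotype CSV** — header `individual,year,trait,value`, long format, at
  most one row per (individual, year, trait); `NA`/empty values skipped.
* **Genotypes** — VCF 4.x with GT (biallelic records; multiallelics
  skipped), or a dosage TSV: first column `individual`, remaining column
  headers `chrom:pos`, cells 0/1/2 alt-allele counts or `NA`.
* **Relationship matrices** — labeled CSV (first column `individual`), or a
  compact `.npz` (ids + row-major values).

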