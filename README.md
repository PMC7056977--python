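# ailrep

Tooling for studying GWAS replication between two cohorts of a
two-founder advanced intercross line (AIL). The package covers the full
desk-scale workflow:

- **`ailrep.simdata`** — synthetic cohorts: AIL pedigrees bred by random
  mating with full-sib avoidance, gene-dropped genotypes (Haldane
  recombination from founder haplotypes), recursive pedigree kinship,
  mixed-model phenotypes (quantitative plus recessive-albino and
  dominant-agouti coat traits), and paired discovery/replication z-scores
  from a shared-plus-study-specific random-effects generative model.
- **`ailrep.qc`** — sample QC (heterozygosity outliers, sex-ratio checks,
  pedigree/GRM kinship concordance, coat-color/genotype concordance) and
  SNP QC (MAF ≥ 0.1, Hardy-Weinberg chi-square p ≥ 1e-6, dosage-r² > 0.9
  pass-through).
- **`ailrep.lmm`** — mixed-model association: centered LOCO GRMs, REML
  null fits via one eigendecomposition and a 1-D variance-ratio search,
  fixed-ratio per-SNP Wald scans, rank-based inverse-normal transform,
  naive permutation genome-wide thresholds, and pooled-sample
  mega-analysis.
- **`ailrep.loci`** — LD r², LD-decay curves, greedy LD clumping of
  significant SNPs, 99% credible sets from summary z-scores, and
  conditional rescans.
- **`ailrep.replication`** — per-locus replication classification, the
  sign test, and maximum-likelihood WC / WC+C random-effects models for
  ascertained summary-statistic pairs (truncated discovery marginal ×
  conditional replication density), with empirical and model-predicted
  replication rates at Bonferroni 0.05/M.
- **`ailrep.power`** — replication power by trait simulation under the
  fitted null variance components, plus a closed-form normal companion.
- **`ailrep.io` / `ailrep.pipeline` / `ailrep.cli`** — text formats
  (dosage TSV, PLINK-1 ped/map, pedigree/phenotype/association TSV),
  YAML configuration, and an orchestrated end-to-end pipeline with a
  checksummed run manifest.

## CLI

All subcommands log to stderr and exit 0 on success, 2 on validation
errors, 1 on runtime errors.

```sh
ailrep simulate --seed 1 --out sim/
ailrep qc --geno sim/genotypes.dosage.tsv --out qc/
ailrep gwas --geno sim/genotypes.dosage.tsv --pheno sim/phenotypes.tsv \
    --trait trait --out assoc.tsv
ailrep perm-threshold --geno ... --pheno ... --trait trait --n-perm 1000
ailrep clump --assoc assoc.tsv --geno ... --p-threshold 1e-5
ailrep credset --assoc assoc.tsv --geno ... --lead chr1.12345
ailrep replicate --disc discA.tsv --rep assocB.tsv --disc-threshold 4.85
ailrep power --geno ... --pheno ... --trait trait --snp chr1.12345
ailrep mega --geno gA.tsv --geno gB.tsv --pheno pA.tsv --pheno pB.tsv --trait trait
ailrep pipeline --seed 1 --out run/        # full two-cohort demo flow
```

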