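# polycomorb

A pipeline for testing whether polygenic risk scores (PRS) built from
psychiatric GWAS summary statistics associate with a general
substance-involvement liability factor and with level-specific substance
involvement, with family-wise control by label-swapping permutation.

## What it does

1. **Synthetic cohorts** (`polycomorb.synthetic_cohort`) — LD-blocked
   biallelic genotypes via a Gaussian-copula haplotype model, discovery GWAS
   summary statistics with a sparse polygenic architecture, demographic
   covariates (56.2% female; age 38.67 ± 9.76; three study sites; three
   ancestry PCs), and five ordinal substance-involvement measures (levels
   0–4 for alcohol, nicotine, cannabis, cocaine, opioids) generated from a
   single latent factor that carries a genetic component.
2. **PRS engine** (`polycomorb.prs_engine`) — per-variant QC (MAF > 0.02,
   call rate > 0.98, exact Hardy–Weinberg p > 1e-6, MHC chr6:25–35 Mb
   exclusion), allele harmonization against the target panel (strand flips
   resolved, ambiguous A/T / C/G pairs dropped), greedy p-value-informed LD
   clumping (r² ≥ 0.10 within 500 kb), and mean weighted allele-count
   scores at the threshold ladder 0.0001 … 1.0 (missing genotypes mean-
   imputed).
3. **Factor model** (`polycomorb.factor_model`) — one-factor normal-theory
   ML confirmatory factor analysis of the five involvement measures, CFI and
   RMSEA, and standardized Thomson regression factor scores ("GENSUB").
4. **Association** (`polycomorb.association`) — OLS of the factor score on
   each standardized PRS with incremental R² over the covariate-only model;
   baseline-category multinomial logistic regression (own Newton–Raphson
   with step-halving, observed-information covariance) of each substance's
   involvement level on PRS; 1-df Wald equality contrasts between level
   coefficients; factor-adjusted reruns.
5. **Permutation** (`polycomorb.permutation`) — max-|z| label-swapping
   permutation: one shared row permutation of the score block per iteration,
   every test refit, the empirical 95th percentile of the null maxima is the
   family-wise significance cutoff.
6. **Pipeline/CLI** (`polycomorb.pipeline`, `polycomorb.cli`) — JSON-driven
   orchestration with per-stage seeds, atomic writes, and a checksummed
   manifest.

## CLI

```bash
polycomorb run-all --config run.json
polycomorb qc --config run.json      # run pipeline through the QC stage
```

A minimal synthetic-mode configuration:

```json
{
  "out_dir": "out",
  "seed": 11,
  "sim": {"n_samples": 2573, "n_snps": 2000, "n_blocks": 100, "gamma": 0.15},
  "permutation": {"n_perm": 1000}
}
```

QC, clumping, threshold and permutation parameters default to the study
values (0.02 / 0.98 / 1e-6; r² 0.10 / 500 kb; ten thresholds; 10,000
permutations at α = 0.05) and can be overridden per block. File mode
replaces `"sim"` with `"inputs": {"sumstats": ..., "genotypes": ...,
"phenotypes": ..., "format": "tsv"|"vcf"}`.

Outputs include per-variant QC statistics, the clump index list, PRS
profiles (one column per threshold), the factor-model summary and scores,
OLS and multinomial results with Wald contrasts, the permutation cutoff
with its null distribution, and report tables (incremental R² by threshold,
substance × threshold × level z-grid with significance flags).

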