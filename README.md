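# ebqtl

Whole-genome epistatic QTL mapping with an empirical-Bayes Lasso.

`ebqtl` fits a sparse Bayesian linear regression over *all* additive and
dominance main effects of a marker bin map plus *all* pairwise
interaction effects (additive x additive, additive x dominance,
dominance x additive, dominance x dominance) — for m bins that is
`2m + 4·m(m-1)/2` candidate variables, over five million at m = 1,619 —
without ever materializing the design matrix. Effects carry a
three-level shrinkage prior (normal coefficients, exponential
per-effect variances with rate lambda, Gamma(a, b) hyperprior on
lambda); inference is cyclic coordinate ascent on the penalized
marginal likelihood with closed-form per-coordinate updates.

The package includes:

- **TSV data model** (`ebqtl.maps`): bin/genetic maps, A/H/B genotype
  matrices, phenotypes, gene catalogs.
- **Design space** (`ebqtl.design`): +1/0/-1 and 0/+1/0 codings, the
  six-block effect index bijection, blockwise on-demand column
  materialization, constant-column exclusion.
- **Solver** (`ebqtl.eblasso`): sparsity/quality factors via the
  active-set posterior (Woodbury), closed-form coordinate updates,
  per-sweep noise-variance and lambda refreshes, multiplicity-calibrated
  admission gate, local exchange polish.
- **Model selection** (`ebqtl.crossval`): the three-step five-fold CV
  over (a, b) with the one-standard-error early stop.
- **Reporting** (`ebqtl.report`): t-tests from the posterior covariance,
  per-effect and OLS-refit total phenotypic variance explained, 20 cM
  single-linkage QTL grouping, gene proximity annotation (20 cM radius,
  2 cM highlight), TSV/edge-list outputs.
- **Simulator** (`ebqtl.simulate`): RIL populations as two-state Markov
  chains under the Haldane map function with selfing map expansion,
  immortalized-F2 crosses, planted sparse main/epistatic effects, and
  power/FDR recovery scoring.

## CLI

Every stage is a subcommand of `ebqtl`; artifacts are plain TSV/JSON.

```sh
# synthetic immortalized-F2 dataset (map, genotypes, phenotypes, truth)
ebqtl simulate --n-chrom 10 --bins-per-chrom 20 --n-ril 240 \
    --n-cross 278 --seed 1 --out-dir runs/sim

# hyperparameter selection by three-step five-fold CV
ebqtl cv --map-path runs/sim/map.tsv --genotypes runs/sim/genotypes.tsv \
    --phenotypes runs/sim/phenotypes.tsv --model main --out-dir runs/cv

# fit (explicit prior, or --best-ab runs/cv/best_ab.json)
ebqtl fit --map-path runs/sim/map.tsv --genotypes runs/sim/genotypes.tsv \
    --phenotypes runs/sim/phenotypes.tsv --a 0.5 --b 0.5 \
    --out-dir runs/fit

# QTL grouping, gene annotation, network edges
ebqtl report --map-path runs/sim/map.tsv --effects runs/fit/effects.tsv \
    --genes genes.tsv --out-dir runs/report

# score recovery of a simulation truth
ebqtl recover --map-path runs/sim/map.tsv --effects runs/fit/effects.tsv \
    --truth runs/sim/truth.json --out runs/recovery.json

# or the whole pipeline from one YAML config
ebqtl run --config config.yaml --out-dir runs/full
```

A `run` config looks like:

```yaml
simulate: {n_chrom: 10, bins_per_chrom: 20, n_ril: 240, n_cross: 278, seed: 1}
model: full           # or main
prior: {a: 0.5, b: 0.5}   # or "cv"
alpha: 0.01
```

## File formats

All inputs are UTF-8 TSV with a header; `#` lines are comments.

- `map.tsv`: `bin_id  chrom  pos_cM [bp_start bp_end]`
- `genotypes.tsv`: `individual_id` + one column per bin, cells A/H/B
- `phenotypes.tsv`: `individual_id` + one column per trait
- `genes.tsv`: `gene_name  chrom  pos_cM`
- `effects.tsv` (output): fixed columns `locus_i family_i locus_j
  family_j beta sd t p_value h2 sigma2_j significant`, with one `#meta`
  JSON line carrying (a, b), mu, sigma2_e, lambda and the refit total
  PVE.
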