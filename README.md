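# phylostruct

Community phylogenetics for two-habitat incidence surveys: per-site
Faith's phylogenetic diversity (PD), standardized phylogenetic structure
indices (NRI/NTI) under a richness-preserving null model, phylogenetic
fuzzy weighting with principal coordinates of phylogenetic structure
(PCPS), and a downstream statistics layer (rank-sum habitat contrasts,
one-sample t tests against zero, Pearson correlation tables with
significance stars, and three-predictor variation partitioning by
adjusted R²). A synthetic data generator produces two-habitat datasets
with tunable phylogenetic clustering/overdispersion for calibration and
testing.

## Library overview

| Module                    | What it does |
|---------------------------|--------------|
| `phylostruct.trees`       | Newick I/O, megatree pruning with optional congener grafting, cophenetic (patristic) distance matrices |
| `phylostruct.community`   | Site × species incidence matrices, subplot unions, species pool |
| `phylostruct.metrics`     | Faith's PD (root path optional), MPD, MNTD |
| `phylostruct.nullmodels`  | Uniform richness-preserving null draws, NRI/NTI, per-site one-tailed significance, habitat structure tallies |
| `phylostruct.pcps`        | Fuzzy weights Q, matrix P, PCoA (sqrt Bray–Curtis or Euclidean), species scores and clade centroids |
| `phylostruct.stats`       | Wilcoxon rank-sum (exact ≤16 obs, no ties), one-sample t, Pearson r with stars, `varpart3` |
| `phylostruct.simulate`    | Yule tree, distance-kernel community assembly, full dataset generator |
| `phylostruct.pipeline`    | `run_all` orchestration writing all output tables |

Typical session:

```python
from phylostruct import (SyntheticConfig, generate_dataset,
                         cophenetic_matrix, ses_table, tabulate_structure,
                         pcps_analysis)

ds = generate_dataset(SyntheticConfig(seed=1))
dm = cophenetic_matrix(ds.tree)
metrics = ses_table(ds.tree, ds.community, n_null=999, seed=1, dm=dm)
table1 = tabulate_structure(metrics)
ordination = pcps_analysis(dm, ds.community, clade_map=ds.clade_map)
```

## Command line

```bash
# generate a synthetic two-habitat dataset
phylostruct simulate --seed 1 --out-dir data/

# full pipeline: metrics, tallies, correlations, varpart, PCPS, contrasts
phylostruct all --tree data/tree.nwk --community data/community.csv \
    --env data/env.csv --clades data/clades.csv \
    --out-dir results/run --nulls 999 --seed 1

# individual stages
phylostruct metrics --tree data/tree.nwk --community data/community.csv \
    --out results/metrics.csv --nulls 999 --seed 1
phylostruct pcps --tree data/tree.nwk --community data/community.csv \
    --clades data/clades.csv --out-dir results/pcps
phylostruct compare --metrics results/metrics.csv --out results/contrasts.csv
phylostruct varpart --metrics results/metrics.csv --env data/env.csv \
    --out results/varpart.csv
```

`phylostruct all` also accepts `--config cfg.toml` with the same keys as
`phylostruct.pipeline.RunConfig`.

## Conventions

- Incidence (presence/absence) is the canonical representation;
  abundance inputs are binarized with a logged warning.
- Taxon names are matched case-insensitively after collapsing
  whitespace to underscores.
- NRI = −(MPD_obs − mean(MPD_null))/SD(MPD_null); positive values mean
  clustering. Significance is one-tailed at α in the direction of the
  observed sign, from the mid-rank null quantile.
- Null model: uniform draws from the all-site species pool holding each
  site's richness fixed (999 draws by default); per-site seeding makes
  results independent of processing order.
- PCPS dissimilarity defaults to the square root of Bray–Curtis;
  Euclidean is available. Axis signs are canonicalized so the
  lexicographically smallest site id scores non-negatively.
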