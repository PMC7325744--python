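# popdiallel

Analytics for hybrid evaluation in a Quality Protein Popcorn breeding
program: a 4-maternal x 12-paternal factorial (diallel, selfs excluded,
reciprocals distinct) grown in a generalized complete block design at two
locations. The package covers the full pipeline on tidy plot-level field
books:

- **`datamodel_io`** — typed domain records (plot observations, trait
  specs, pedigree, amino-acid profiles), CSV readers/writers, YAML
  configuration with the default selection-intensity weights.
- **`synthetic_data`** — multi-trait diallel trial simulator (maternal/
  paternal GCA, SCA, location, location-by-genotype, and plot-error
  variance components with a factor-structured genetic correlation,
  including the negative expansion-volume vs. yield correlation), an
  amino-acid profile simulator with known inheritance modes, and a default
  12-inbred pedigree whose 44 crosses populate all five heterosis
  categories. All downstream stages are testable without any external data.
- **`anova_varcomp`** — two-way location x treatment ANOVA with Type II
  sums of squares by nested model comparison (robust to missing plots and
  missing hybrids), variance components by expected-mean-square inversion,
  and plot-basis heritability/repeatability ratios.
- **`combining_ability`** — hybrid cell means, maternal/paternal general
  combining ability, specific combining ability with the exact
  reconstruction identity `mu + g_m + g_p + s = cell mean`, and
  contrast-based standard errors.
- **`ranking_index`** — the weighted rank-summation selection index
  `X_h = sum_i (y_ih/y_imax - 1)^2 I_i (sd_ih/sd_imax)` with orientation
  transforms (rot susceptibility complemented), per-trait contribution
  decomposition, and pessimistic imputation of missing traits.
- **`heterosis_pedigree`** — five ordered pedigree-distance categories
  (pseudo-self < same-popcorn < same-QPM < same-pool < complete hybrid),
  Tukey-Kramer HSD from the studentized-range distribution, and the
  stepwise category-trend report with a monotonicity flag.
- **`trait_structure`** — pairwise Pearson correlation/covariance matrices
  on hybrid entry means with significance stars, and standardized
  regression path coefficients from correlation-matrix normal equations.
- **`protein_quality`** — group fold changes, lysine as a percentage of
  total protein, popping loss/retention, cross-method correlation screening
  with the 0.700 flag, additive/dominant/over-dominant inheritance
  classification, and dietary-requirement fractions.

## CLI

All commands are subcommands of `popdiallel`:

```bash
# generate a full synthetic dataset (fieldbook, pedigree, truth, amino acids)
popdiallel simulate --seed 1 --out data/

# per-trait ANOVA with variance components and heritability
popdiallel anova data/fieldbook.csv --trait el --factor maternal --out anova.json

# combining-ability report (GCA + SE + heritability, SCA matrix)
popdiallel diallel data/fieldbook.csv --trait ev --out diallel.json

# rank hybrids by the weighted index (per-trait contribution columns)
popdiallel rank data/fieldbook.csv --out rank.csv

# pedigree heterosis categories and the category trend test
popdiallel heterosis data/fieldbook.csv data/pedigree.csv --trait hgw --out trend.json

# trait correlation / covariance structure
popdiallel correlate data/fieldbook.csv --out corr.json

# amino-acid inheritance classification and method correlations
popdiallel protein data/amino.csv --hybrid hybrid --maternal maternal \
    --paternal paternal --out protein.json
```

Field books are long/tidy CSV (`location, block, genotype, maternal,
paternal, trait, value`); proportions are stored in [0, 1] and a trailing
`%` on a trait name marks percent-scale input.

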