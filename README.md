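# microtraits

Comparative analysis of the major trait dimensions of bacteria and archaea:
cell radial diameter *d*, genome size *G*, maximum growth rate μ_max, and
rRNA operon copy number (RRN). The central question is whether these traits
are correlated across species — as they would be if a single
oligotrophy–copiotrophy axis organized microbial ecological strategies — or
whether they vary as independent dimensions.

The package provides, as a tested library plus numbered analysis drivers:

- **Condensation** of heterogeneous trait records (one to thousands per
  species) to one row per species: natural-scale averaging of quantitative
  traits after robust outlier screening (modified z-score > 3.5 on log10
  values, MAD-based, applied at ≥ 4 records), strict-majority rule for
  categorical traits (ties → missing), and exclusion of intracellular
  species and mycoplasmas, whose reduced genomes have nothing to do with
  oligotrophy.
- **Temperature adjustment** of maximum growth rates: the residual
  g̃ = log10(μ_max) − (a·T + b) from an OLS fit of log growth rate on growth
  temperature T (reference convention a = 0.0105 log10(h⁻¹)/°C,
  b = −1.2003), so that species cultured at different temperatures become
  comparable.
- **Trait correlations**: squared Pearson correlations r² of the
  log10-scaled traits over pairwise-complete species.
- **AIC model selection**: nine OLS models for g̃ with successively more
  terms — linear and quadratic log-diameter, log-genome-size, habitat as a
  dummy-coded factor, and their crossings — fitted on a single
  complete-case row set so AIC values are commensurate, with a variance
  partition of the winning model into habitat and nonlinear-diameter
  shares.
- **PGLS from first principles**: the 7-rank taxonomy (superkingdom …
  species) is read as a rooted tree with a star polytomy at every node and
  unit branch lengths; under Brownian trait evolution the covariance of two
  species is V[i,j] = number of leading ranks shared (V[i,i] = 7).
  Generalized least squares, β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y solved through a
  Cholesky whitening of V, measures correlation of trait *divergences*
  rather than of present-day tips.
- **A synthetic-data generator** that emulates the statistical structure of
  a compiled trait database — correlated Brownian traits on a random
  taxonomy, habitat offsets and a quadratic diameter response on the growth
  score, temperature-dependent μ_max, per-trait species coverage, and a
  noisy multi-record layer — so every pipeline stage is testable without
  external data.

## Worked example

The numbered drivers run the full analysis on the generator's default,
study-scale conditions (3,466 species, ~618 with growth data):

```bash
python analysis/01_simulate_dataset.py      # records.csv, species_true.csv
python analysis/02_condense_species.py      # species.csv
python analysis/03_temperature_adjustment.py
python analysis/04_trait_correlations.py
python analysis/05_growth_models.py
python analysis/06_phylogenetic_regression.py
```

Output of step 03 (seed 0):

```
temperature regression (refit): log10(mu_max) = 0.0104*T -1.2470
  r^2 = 0.112, n = 616 species
```

Growth rates are ~2.4% faster per °C of growth temperature, explaining 11%
of the variance in log growth rate. Step 04 then prints the correlation
table:

```
  g_adj              x cell_diameter_um   r^2 = 0.0057 (n = 610)
  g_adj              x genome_size_bp     r^2 = 0.0002 (n = 611)
  g_adj              x rrn_copies         r^2 = 0.2779 (n = 480)
  cell_diameter_um   x genome_size_bp     r^2 = 0.0006 (n = 3323)
  cell_diameter_um   x rrn_copies         r^2 = 0.0060 (n = 2614)
  genome_size_bp     x rrn_copies         r^2 = 0.1301 (n = 2619)
growth rate, diameter and genome size share <2% of variance pairwise:
independent dimensions
```

Growth rate, diameter and genome size are near-independent; only RRN
carries appreciable shared variance with growth rate (r² ≈ 0.28) and
genome size (r² ≈ 0.13). Step 05 ranks the nine models and finds the
additive quadratic-diameter + habitat model best by AIC:

```
best model by AIC: 7. growth ~ (cell_diam + cell_diam^2) + habitat (n = 431)
variance partition: habitat 11.4%, nonlinear diameter 7.9%, total 18.4%
oligotroph vs copiotroph on g_adj:            standardized difference +7.48
oligotroph vs copiotroph on cell_diameter_um: standardized difference -0.24
oligotroph vs copiotroph on genome_size_bp:   standardized difference +0.11
oligotroph vs copiotroph on rrn_copies:       standardized difference +2.19
```

The fastest growth rates sit in the midrange of cell diameters (negative
quadratic term), habitats differ in mean growth capacity, and labelled
oligotrophs and copiotrophs separate cleanly on the growth dimension (and
RRN) but not on diameter or genome size. Step 06 refits the main pairs by
PGLS and reports a near-circular half-max density contour on the
standardized diameter × genome plane (axis ratio 1.05), i.e. no
interaction between the two size dimensions.

The same pipeline runs as one command, from a record CSV or the generator:

```bash
microtraits run --outdir results/run --seed 0
microtraits simulate --n-species 500 --seed 1 --out records.csv
microtraits condense --input records.csv --out species.csv
```

External record tables are read as CSV with either seven taxonomy columns
(`superkingdom,…,species`) or a single semicolon-delimited
`d__…;p__…;…;s__…` string; see `microtraits --help` for the
subcommands (`simulate condense adjust correlate models pgls contours run`).

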