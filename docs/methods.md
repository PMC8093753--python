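# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Species condensation

Trait databases report records at the level of genotypes or 16S
phylotypes; the analysis unit is the species. Quantitative traits (cell
radial diameter, genome size, maximum growth rate, growth temperature,
rRNA operon copy number) are condensed by the arithmetic mean on the
natural scale; categorical traits (habitat, shape, trophic label) by
strict majority, with ties left missing rather than resolved by an
arbitrary rule — fabricating a value would bias downstream factors.
Boolean flags (intracellular, mycoplasma) condense as any-record-True,
which is conservative for the exclusion filter they feed.

Gross errors are screened per species and trait before averaging with a
modified z-score on log10 values: flag x when
|0.6745·(log10 x − median)/MAD| > 3.5, applied only when a species has at
least 4 values for the trait and the MAD is positive. The threshold 3.5 is
the standard robust-outlier convention; the log scale matches the
lognormal error structure of these traits; the MAD keeps the screen
insensitive to the outlier itself. With fewer than 4 records no screening
is attempted — a deliberate limitation: a 50-fold error among two records
cannot be identified from within the species, which is why curated
compilations apply upstream correction tables. The generator's default
gross-error rate is correspondingly low (see below).

Diameter ranges ("0.5–1.5") resolve to the arithmetic midpoint; sources
rarely state what a range represents, and the midpoint is the neutral
choice. For rods the value is the radial (width) dimension, which makes
cocci and rods comparable as surface-to-volume descriptors.

Species living inside eukaryote cells, and mycoplasmas as a group, are
excluded by default (`include_intracellular=False`): their genome
reduction reflects host association, not resource strategy, and their
growth rates are conditioned by the host. Mycoplasma membership is taken
from the record flag or a genus-name match.

## Temperature adjustment

Maximum growth rates are measured at species-specific culture
temperatures, and rates are faster when cultures are warmer. The analysis
variable is therefore the residual

    g̃ = log10(μ_max) − (a·T + b),

the deviation, in log10 units, above or below the expected maximum growth
rate at the species' growth temperature. By default a and b are refit by
OLS on the table at hand (one point per species, consistent with a
species-level dataset); `mode="fixed"` applies the reference coefficients
a = 0.0105 log10(h⁻¹)/°C, b = −1.2003 instead, for applying the published
convention to new data. Species without a recorded growth temperature are
dropped from growth-rate analyses rather than imputed. Nonlinear thermal
performance curves (Arrhenius, Ratkowsky) are out of scope; over the 4–50
°C range of mesophile culture data the linear log-scale fit is the
convention this package reproduces.

## Taxonomy tree, Brownian covariance, PGLS

The seven-rank taxonomy is interpreted literally as a phylogeny: a root
above the superkingdoms, a star polytomy at every node, unit branch
lengths. Every species then sits at depth 7, and under Brownian trait
evolution with rate σ² the covariance of species i and j is
σ²·V[i,j] with V[i,j] the number of leading ranks shared (0–6; 7 on the
diagonal). Placing the root above the superkingdoms makes inter-domain
covariance exactly 0. V is positive definite for any taxonomy with unique
species names (V = I + a tree covariance), but can be near-singular with
many congeneric species, so the Cholesky factorization falls back to a
1e−10 diagonal jitter before failing.

PGLS minimizes (y − Xβ)ᵀV⁻¹(y − Xβ). The solve whitens y and X by the
lower-triangular Cholesky factor of V — the explicit inverse appears only
in test oracles. The Gaussian log-likelihood is profiled over the residual
variance (σ̂² = RSS/n), giving

    ℓ̂ = −(n/2)[ln(2π·RSS/n) + 1] − ½ ln|V|,
    AIC = −2ℓ̂ + 2(p + 1),

where p counts mean parameters and the +1 counts the variance. Coefficient
covariance is σ̂²(XᵀV⁻¹X)⁻¹ with σ̂² = RSS/(n − p), and confidence
intervals use the t distribution on n − p df; under a correctly specified
V these intervals attain nominal coverage (checked by simulation in the
acceptance suite). No Pagel's-λ or other branch-length transform is
estimated: the tree and its unit branch lengths are part of the model
definition here, and a λ extension would only interpolate toward OLS.

R² for PGLS is defined as the squared correlation between fitted and
observed values in the whitened space, which reduces exactly to the usual
1 − RSS/TSS for OLS with an intercept. Known quirk of this convention: for
strongly non-spherical V the whitened intercept direction is not constant,
and the squared correlation can be substantially larger than an
"explained variance" reading would suggest (visible in the
diameter–genome PGLS comparison). The PGLS *slopes* are the interpretable
divergence-level quantities; alternative R² conventions would change the
number but not the fit.

The nine-model suite is OLS, not PGLS, matching the convention of the AIC
table it mirrors. Quantitative predictors are log10-scaled; polynomial
diameter terms are centered on the mean of log10 d before squaring to
reduce collinearity (R², AIC and df are invariant to centering). Habitat
is dummy-coded against the alphabetically first level; only AIC, R² and df
are contract outputs, since coefficients depend on the reference level.
Model 9's `(d + d²) * G * habitat` crossing expands to all products of
{1, d, d²} × {1, G} × {1, habitat dummies}, i.e. 6L mean parameters for L
habitat levels, which reproduces the df accounting of the convention it
follows. All nine models are fit on the identical complete-case row set so
AIC values are commensurable; with a single habitat level the factor
models are skipped with a warning.

Group separation between labelled oligotrophs and copiotrophs reports
means on the analysis scale, a pooled-SD standardized difference (positive
= copiotrophs higher), and an overlap fraction (mean share of each group
inside the other's central 90% interval). Density contours use a 2-D
Gaussian product kernel with the bivariate normal-reference bandwidth
h_j = σ_j·n^(−1/6) per axis, evaluated on a 128×128 grid padded by 3
bandwidths, with contour polylines extracted at fractions
{0.25, 0.5, 0.75} of the density maximum; a level of 1.0 degenerates to
the mode. Note that circularity is only meaningful on standardized axes
(driver 06 standardizes before reporting the axis ratio); on raw log axes
the contours are axis-aligned ellipses whenever the marginal spreads
differ.

## Synthetic-data generator

The generator produces a record-level trait database with the statistical
structure the analysis assumes, at a configurable scale. Defaults describe
the study-scale conditions: 3,466 species, of which ~618 (82.17%
growth-coverage gap) carry growth-rate and temperature data, ~79% carry
RRN, and all carry diameter and genome size; habitat is known for ~74.5%.

**Taxonomy.** Species are grouped bottom-up into genera, families, …,
superkingdoms with group sizes 1 + Poisson(b − 1) at configured means
b = (21, 2.5, 2.5, 2.5, 2, 2.6) for ranks 1–6, yielding a flat-topped
taxonomy (2–3 domains, ~45 phyla, ~1,350 genera at 3,466 species) like a
rank-normalized prokaryote taxonomy restricted to cultured species.

**Traits.** Four latent log-scale traits (growth score, log10 d, log10 G,
log10 RRN) evolve as correlated Brownian motion on the taxonomy tree:
independent standard-normal branch increments are mixed through the
Cholesky factor of the target correlation matrix ρ, so the tip-level
cross-trait correlation is ρ while each trait retains phylogenetic
autocorrelation. Branch variances carry a depth profile (default weights
0.2…2.2 from superkingdom to species, normalized to preserve tip
variance): divergence concentrates among recent splits. With a
depth-uniform profile, a handful of deep-clade draws dominate
cross-species summaries — the sample correlation of two independent traits
then has an effective sample size near the number of phyla, and "zero
correlation in, near-zero r² out" fails for a quarter of random seeds at
n ≈ 3,500. The shallow-concentrated default keeps strong genus/family
phylogenetic signal (PGLS and OLS still disagree measurably) while making
tip-level summaries stable, which is the property the generator exists to
provide.

Brownian rates are set so the expected tip *sample* standard deviations
are ~0.36 (growth score), 0.25 (log d: diameters mostly 0.2–3 μm), 0.35
(log G), 0.33 (log RRN); the rate-to-sample-variance factor (≈ 6.6–6.85×
the per-branch rate, not 7×) accounts for the average shared depth between
species pairs. Default ρ entries are chosen so the *realized* pairwise r²
of the analysis variables center on the compiled-database values (growth
score–RRN 0.63, genome–RRN 0.36, diameter–genome 0.11, …); the
growth-score entries are inflated by ≈ 1/0.91 because habitat offsets and
the quadratic diameter term add variance to g̃ that attenuates its
correlations with the other traits.

**Growth structure.** The growth score gains an additive habitat offset
(eight habitat categories, offsets −0.198…+0.198 log units, host-endotherm
habitats fast and open marine water slow; ≈ 11% of g̃ variance) and a
quadratic response to centered log diameter (coefficient −1.3 per
(log10 μm)², ≈ 6% of variance: fastest growth in the diameter midrange).
Growth temperature is uniform on 4–50 °C and
log10 μ_max = 0.0105·T − 1.2003 + score, which makes the refit temperature
regression land near r² = 0.11. Trophic labels mark the tails of the
score distribution (bottom/top deciles → oligotroph/copiotroph) among
species with growth data, mirroring that literature labels track growth
capacity. Intracellular (1%) and mycoplasma (0.5%) species get 0.3 log
units smaller genomes, exercising the exclusion filter.

**Record layer.** Record counts per species are geometric with mean 3;
values get lognormal noise (SD 0.01–0.05 log units per trait; ±1 °C for
temperature), are deleted with probability 0.05, and with probability
0.002 per value are multiplied or divided by 50 — a gross error, with
ground truth kept in `outlier_*` columns so detection rates are testable.
The low default rate emulates a compilation whose non-credible records
were already corrected upstream; the robust screen can only catch gross
errors in species with ≥ 4 records, so higher rates visibly attenuate the
quadratic-diameter signal through high-leverage diameter errors.
Categorical values contradict the species value with probability 0.03 to
exercise majority rule.

**What the generator does not emulate,** and hence what passing tests do
not show about real data: source-specific measurement conventions and
unit-harmonization errors across merged datasets; correlated missingness
(in real compilations, trait coverage is structured by data source, so
pairwise ns are not products of marginal coverages); within-species strain
variation beyond iid noise; taxonomy mis-assignment; and any real
phylogeny — trait divergence here follows the taxonomy tree by
construction, so PGLS is correctly specified in a way it never is with
real trees.

## Numerical conventions and edge cases

- Whitening via `numpy.linalg.cholesky`; 1e−10 diagonal jitter fallback;
  symmetric-check tolerance 1e−8.
- Rank-deficient designs raise with the offending column names (QR with
  pivoting); a perfect fit (RSS = 0) raises rather than returning −∞ AIC.
- A flat growth-rate response (zero variance in log μ_max) returns slope
  0 and r² 0; zero variance in T is an error (slope unidentifiable).
- Correlation cells with fewer than 3 complete pairs are reported missing;
  zero-variance axes are errors for contours.
- `rrn_copies` condenses to an integer ≥ 1 (nearest-integer rounding).
- All randomness flows through `numpy.random.default_rng` seeded from a
  single config seed; identical configs give bit-identical output files,
  and output CSVs carry the seed and a config hash in a comment header
  (the output directory is excluded from the hash so relocated reruns
  stay byte-identical).

## Problem sizes

The test suite runs the GLS oracles at n ≤ 50 (100 problems each), the
covariance oracle at 1,000 random taxonomies, Brownian calibration at
10,000 replicates on 20 tips, interval coverage at 500 replicates on 200
tips, model recovery at 200 replicates of n = 385, and the end-to-end null
reproduction at the full 3,466-species scale — sizes chosen so each check
has the statistical resolution its tolerance needs. The acceptance script
repeats the full-scale pipeline once and the model-recovery simulation at
50 replicates.
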