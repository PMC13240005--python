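# Methods

This note documents the models, conventions and numerical choices behind
`cohortenv`, in the order data flows through the package.

## Survivorship model and demographic matrix

Each birth-year cohort is assumed to decline exponentially with age (Type III
survivorship), so log abundance is linear in age:

    log N(a) = N0 + z · a,   z ≤ 0 on the true scale.

`fit_survivorship` is plain OLS of log abundance on age. The intercept is
taken **at age 0** (not at the first observed age), so `N0` is comparable
across generations regardless of which ages happened to be sampled. The log
base is natural by default, configurable and recorded in every output; only
`N0` changes under a base change (by the constant log ratio), `z` rescales,
and all correlation-based downstream results are invariant.

Inclusion rules (defaults): drop cells at age 1 (individuals can be smaller
than the 1-mm sieve mesh) and above age 10 (older individuals are vanishingly
rare in collections); keep generations born in or after 1999 with at least
four distinct record years remaining. Four points is the minimum to
characterize a line and leave room for a residual; the filter report counts
what each rule removed, and the counts are additive by construction.

Zeros and gaps: a cohort absent from a sample at ages 2–10 is treated as
*missing* (limited sampling), not as a true zero; missing `N_a` values are
imputed from the generation's own fitted line, `N0 + z·a`, with per-cell
provenance flags. The alternative of using fitted values everywhere is
available (`mode="fitted"`); the default keeps observed cells observed.
Duplicate observations of one (year, age) cell are averaged on the raw scale
before the log transform.

Density dependence is diagnosed by Pearson correlations of `N0` with `z` and
with each `N_a`. Under density-dependent mortality the signature is
r(N0, z) < 0 with r(N0, N2…N4) > 0: abundant cohorts start high and die
faster, so the association of `N_a` with `N0` decays with age and crosses
zero near age 1/|slope of z on N0|.

## Seasonal environmental features

Seasons follow the regional hydrological convention: winter November–April
(November and December belong to the *following* year's winter), spring
May–June, summer July–August, autumn September–October. A missing month is an
error, never a silently shortened season — a 4-month winter would bias every
comparison that uses it.

The 24 features per generation are 4 variables × 4 seasons of the birth year
plus {air, water} temperature × 4 seasons averaged from birth year to last
detection year. The lifespan average is the **mean of yearly seasonal means**
(equal weight per year), not a pooled monthly mean; the two differ only when
months are missing, which is an error anyway, but the convention is fixed and
documented. Column order is variable-major, season-minor, birth-window
columns before lifespan columns.

## BIO-ENV

The demographic matrix is converted to Euclidean distances between
generations **without** standardizing its columns by default (the demographic
parameters are all on the log-abundance scale; a flag enables z-scoring and
is recorded). Environmental columns **are** z-scored by default — their units
are incommensurable — before distance construction.

Match quality is the Mantel correlation: Pearson (default) or Spearman
correlation of the two matrices' strict lower triangles (n(n−1)/2 pairs). The
search is exhaustive over all 2^p − 1 subsets. The engine precomputes, for
each column j, the condensed vector of squared coordinate differences d²_j;
squared Euclidean subset distances are additive, d²_S = Σ_{j∈S} d²_j, so the
columns are split into a low and a high half, partial sums over all masks of
each half are tabulated once by dynamic programming, and each subset costs a
single vectorized row addition plus correlation bookkeeping. At p = 24 and
n = 16 the full 16,777,215-subset run takes a few seconds on one CPU.

Ties on the correlation break toward the smaller subset, then toward the
lexicographically earlier column combination (a 10⁻¹² tolerance absorbs
floating-point ties between proportional subsets). A per-size table of best
subsets is reported alongside the overall winner. No permutation p-value is
attached to the winning subset: after an exhaustive search over 16.8 million
candidates the naive Mantel test is badly selection-biased, and
selection-aware inference is out of scope.

## Redundancy analysis

Y (demographic matrix) is centered — optionally scaled to unit column
variance; both settings are recorded, and axis-share results are worth
inspecting under both since the response columns mix log abundances with a
rate. X (selected environmental columns) is centered and standardized;
linearly dependent columns are dropped with a warning. Y is projected onto
the column space of X by least squares; the SVD of the fitted matrix gives
canonical axes, with eigenvalues on the variance scale s²/(n−1) so that
constrained + residual eigenvalues sum to the total inertia (the sum of Y's
column variances). Axis shares are reported both as percent of total and as
percent of constrained inertia.

Permutation inference (all p-values use the add-one rule, so a permutation
test never reports exactly zero; for n with n! below the requested
permutation count the whole-model test switches to exact enumeration):

* **Model**: pseudo-F = (constrained inertia/q)/(residual inertia/(n−q−1)),
  rows of Y permuted uniformly.
* **Axes**: forward sequential tests — axis k is tested after residualizing Y
  and X on the first k−1 fitted site-score axes, with the first partial
  eigenvalue over the full model's residual mean square as statistic and the
  residualized Y's rows permuted. Raw p-values are reported without
  monotonization.
* **Terms**: marginal tests — each column against the model containing all
  others, permuting residuals of the reduced model with the reduced fitted
  values held fixed.

The permutation functions canonicalize row order by label before drawing
permutations, so p-values are reproducible under a seed and invariant to the
order rows arrive in.

## Box-Cox and trend smoothers

Biomass analyses run on the Box-Cox scale (x^λ − 1)/λ with λ by profile
maximum likelihood (Brent search; tests pin it against a dense grid oracle).
The inverse transform is exact and domain-checked. The regional temperature
covariate for a survey year is the mean of the **five preceding years**,
survey year excluded (an inclusive-window flag exists because either reading
of "preceding" is defensible; exclusion is the literal one and the default).

Trend structure is fitted by per-group penalized cubic B-splines: 10 knots by
default, interior knots at quantiles of the predictor, which is normalized to
[0, 1] internally so fits are exactly invariant to affine rescaling of x. The
penalty is the integrated squared second derivative (curvature), computed
exactly by two-point Gauss quadrature per knot interval — its null space
contains straight lines for any knot placement, so noise-free linear data are
recovered with effective df → 2. The smoothing parameter minimizes GCV =
n·RSS/(n − edf)² on a log grid, ties resolving toward the heavier penalty. A
site factor, when supplied, enters as ridge-penalized intercepts in the same
penalized least-squares system, the ridge weight selected jointly by GCV — a
shrinkage approximation of a random intercept. These smoothers reproduce
trend *structure* (shape, direction, group contrasts); they are not a
coefficient-level reproduction of any particular mixed-GAM implementation,
and their metadata says so.

## Synthetic-data generator

The generator emulates a two-decade age-structured monitoring study plus a
nine-decade compiled biomass archive. All randomness flows from a single seed
through fixed per-stage substreams, so identical configs give byte-identical
tables.

**Environment**: monthly climatology (cosine seasonal cycles; Barents-like
means and amplitudes), a linear warming trend on the temperatures (0.03
°C/yr), a persistent yearly AR(1) temperature anomaly (SD 0.6 °C, φ = 0.6 —
multiannual thermal regimes, without which lifespan-averaged covariates carry
almost no between-generation signal), a shared monthly anomaly coupling air
and water temperature, and independent monthly noise.

**Cohorts**: log N0 = 6.0 + 1.0·(spring water temp) + 0.6·(spring wind) +
ε(0.2), covariates centered across generations; z = −0.55 + 0.2·(lifespan
summer water temp) − 0.2·(centered log N0) + η(0.035), truncated at 0 from
above (truncation is logged; under the defaults it is rare). The density
slope of −0.2 places the zero crossing of the N0–N_a coupling at age 5, so
the young age classes (N2–N4) associate positively with N0 and the old ones
negatively — the qualitative pattern long-term mussel monitoring reports.
The mortality covariate uses a fixed horizon (birth + max age) rather than
the realized last-detection year, deliberately breaking the circularity
between simulated survival and observed lifespan; the observational analysis
of course uses last detection.

**Observation**: sampled area = 5 cores × 0.1 m² (the upper end of a 3–5
cores-per-transect design); counts are Poisson(density × area)/area — the
simplest observation model consistent with count data — and cohorts drawn as
zero are *absent* from the table, matching how field samples record cohorts
and the missing-not-zero imputation policy upstream. Age-1 rows are retained
with probability 0.5; ages up to max age + 2 are emitted so the age filter
has something to drop. Sampling years are 2001–2007, 2009–2013, 2016–2018
and 2020; with births 1996–2015 the inclusion filters retain the 16
generations born 1999–2014 (in a minority of seeds a Poisson zero costs the
youngest cohort its fourth record year, and 14–15 are retained — that is the
design's real behavior, not a defect).

**Biomass archive**: 173 records at up to 62 sites across seven survey
periods (19/8/54/27/10/37/18 records from the 1930s to 2010–2020), built on
the Box-Cox scale (λ = 0.22) from a grand mean, a survey-specific longitude
slope (negative only in the 1960–1961 survey), a period-specific slope on
the 5-year-preceding temperature (strong before 1975, weak after), site
random intercepts and Gaussian noise, then back-transformed to kg/m². The
annual temperature index is a multidecadal cosine around 4.15 °C (peak 1945,
so mid-century warm, 1970s–80s cold) plus noise.

**What the generator does not emulate**: spatial metapopulation structure,
larval dispersal, species mixtures, length-structured growth, measurement
error in age reads, temporal autocorrelation of observation errors, and any
non-Poisson overdispersion of counts. Passing recovery tests therefore show
that the *analysis chain* is correct and adequately powered under the stated
design, not that real data meet these assumptions.

## Effect sizes and problem sizes used in the test suite

The generator's effect sizes were fixed once, by design analysis: strong
enough that the drivers the analysis is meant to detect are detectable
through a 16-generation Mantel screen (a weak instrument — 120 distance
pairs), with the density slope set by the observed pivot age of the N0–N_a
coupling and the axis-share separation chosen so the recruitment axis clearly
dominates the constrained ordination. Under these defaults, across 100
seeds: a generating spring driver enters the BIO-ENV best subset in ~98%,
and the axis-1 loading sign pattern (N0, N2–N4 against z) holds in ~83% of
replicates under response scaling.

Replicated property tests run the subset search on a 12-column panel
(exhaustive within the panel) rather than the full 24 columns, keeping 100
replicates to seconds; the full 24-column enumeration is exercised once per
run of the acceptance script and once in the test suite, where it completes
in well under a minute. Permutation-calibration tests use 500 null replicates
with 199 permutations each at n = 16. The acceptance script uses 9999
permutations for the whole-model test and 999 for axes and terms.

## Known limitations

* The BIO-ENV engine is O(2^p) in memory-light time but still exponential;
  the default guard refuses p > 24 without an explicit override.
* The forward axis tests use the full-model residual mean square as a common
  denominator; this is one of several defensible conventions and is
  documented rather than configurable.
* The smoother's intervals are conditional on the selected smoothing
  parameters (no selection uncertainty), and the site term is shrinkage, not
  a true integrated random effect.
* `z` truncation at 0 makes the recruitment–mortality coupling mildly
  nonlinear near zero; under the default effect sizes truncation is rare
  enough to ignore.
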