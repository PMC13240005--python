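# cohortenv

Cohort demography and environmental association analysis for age-structured
population monitoring, built around the analysis chain used in long-term
studies of littoral bivalves (blue mussels of the subarctic Barents Sea
coast): from shell-ring age reads to per-generation survivorship parameters,
and from those to the environmental drivers of recruitment and survival.

## What it does

**Survivorship demography.** Mussels follow a Type III survivorship curve, so
the abundance of a birth-year cohort ("generation") declines exponentially
with age. For each generation the package fits

    log N(a) = N0 + z · a

by ordinary least squares, where `z` (the slope) is a proxy of the per-year
death rate and `N0` (the intercept at age 0) a proxy of recruitment success.
Inclusion rules mirror long-term monitoring practice: age-1 individuals are
unreliable at the sieve size and dropped, individuals older than 10 years are
ignored, and a generation enters the analysis only if recorded in at least
four different years. Sampling gaps in the age-specific abundances N2–N10 are
imputed from the fitted line, and the demographic matrix
(N0, z, N2…N10 per generation) is screened for density dependence — abundant
cohorts starting high but dying faster.

**Seasonal environmental features.** Monthly station series (air and
sea-surface temperature, wind speed, wave height) are reduced to 24 features
per generation: the four variables averaged over each season of the birth
year (16), plus air and water temperature per season averaged over the
generation's observed lifespan (8). Seasons follow the Barents Sea
convention: winter = November–April (November/December attributed to the
following year), spring = May–June, summer = July–August, autumn =
September–October.

**BIO-ENV.** The demographic matrix is turned into a Euclidean distance
matrix between generations and compared — by Mantel correlation of the
vectorized lower triangles — against the distance matrices of **all
16,777,215 non-empty subsets** of the 24 environmental features. The engine
exploits the additivity of squared Euclidean distances
(d²_S = Σ_{j∈S} d²_j) with partial-sum tables over half-masks, so the full
enumeration takes seconds, not days.

**Redundancy analysis.** The selected environmental subset constrains an RDA
of the demographic matrix, written from first principles: project Y on the
column space of X, SVD the fitted matrix, report canonical eigenvalues as
shares of total inertia, and assess the model, each canonical axis and each
constraint by permutation (9999 permutations by default, add-one p-values,
exact enumeration for tiny n).

**Trend models.** Box-Cox machinery (profile-likelihood λ, exact inverse),
the "mean temperature of the five preceding years" covariate, and per-group
penalized cubic B-spline smoothers (curvature penalty, GCV, optional
ridge-penalized site intercepts) for long-term biomass trend structure.

**Synthetic data.** A seeded generator reproduces the statistical structure
the analysis assumes — environmentally driven recruitment (spring water
temperature and wind), environmentally driven survival (summer water
temperature over the lifespan), density-dependent mortality coupling N0 and
z, Poisson observation of cores, partial detection of age-1 individuals, and
a multi-decade biomass archive of 173 records at 62 sites generated on the
Box-Cox scale — so every stage is verifiable against known ground truth.

## Worked example

```python
from cohortenv import (SimulationConfig, simulate_environment, simulate_cohorts,
    sample_ages, build_generation_matrix, filter_generations, impute_missing,
    last_detection_years, build_env_matrix, euclidean_distances,
    exhaustive_bioenv, fit_rda, permutation_test_model)
from cohortenv.demography import fit_all_generations

cfg = SimulationConfig(seed=1)
env = simulate_environment(cfg)
truth = simulate_cohorts(env, cfg)
samples = sample_ages(truth, config=cfg)

gm, report = filter_generations(build_generation_matrix(samples))
print(f"{report.surviving} generations retained (born "
      f"{gm.index.min()}-{gm.index.max()})")

fits = fit_all_generations(gm)
dm = impute_missing(gm, fits)
f03 = fits[2003]
print(f"generation 2003: N0 = {f03.n0:.2f}, z = {f03.z:.3f}, R^2 = {f03.r_squared:.3f}")

last = last_detection_years(gm)
features = build_env_matrix(env, [(int(b), int(last[b])) for b in gm.index])
biotic = euclidean_distances(dm.data, standardize=False)
best = exhaustive_bioenv(biotic, features)
print(f"BIO-ENV: {best.total_subsets:,} subsets; best r = {best.best_r:.3f}")

X = features[list(best.best_subset)]
rda = fit_rda(dm.data, X)
p, F, *_ = permutation_test_model(dm.data, X, n_perm=9999, seed=1)
print(f"RDA1 {rda.proportion_total[0]:.0f}% of inertia, "
      f"RDA2 {rda.proportion_total[1]:.0f}%; model F = {F:.2f}, p = {p:.4f}")
```

prints

```
16 generations retained (born 1999-2014)
generation 2003: N0 = 6.78, z = -0.677, R^2 = 0.999
BIO-ENV: 16,777,215 subsets; best r = 0.633
RDA1 79% of inertia, RDA2 7%; model F = 6.54, p = 0.0017
```

The 16 retained generations are exactly those with four or more record years
at ages 2–10; the near-perfect R² reflects the log-linear decline; the
selected subset contains the generating spring drivers, and the constrained
ordination is dominated by a significant first axis on which recruitment
(N0, N2–N4) opposes mortality (z).

The same chain is available from the shell:

```bash
cohortenv pipeline --seed 1 --outdir runs/demo    # writes a run manifest
cohortenv simulate --seed 1 --outdir fixtures     # just the synthetic tables
cohortenv bioenv --demographic-matrix dm.csv --env-features ef.csv --out best.json
```

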