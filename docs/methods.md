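# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical decisions, and what the synthetic generators do
and do not emulate.

## Neutral differentiation (popgen)

θ is the Weir–Cockerham (1984) moment estimator. For each allele at a locus
scored in r populations with locus-wise sample sizes n_i, allele frequencies
p_i and observed heterozygote frequencies h_i, the components are

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − (r−1)s²/r − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − (r−1)s²/r − (2n̄−1)h̄/(4n̄) ]
    c = h̄/2

with n̄ the mean sample size, n_c the unequal-sample-size correction, p̄ and
h̄ sample-size-weighted means and s² the weighted variance of frequencies.
Components are summed over alleles and loci; the multilocus estimate is the
ratio of sums θ = Σa / Σ(a+b+c). Decisions:

* **Missing data** are deleted locus-wise (an individual missing at a locus
  is excluded from that locus only) — the standard convention for this
  estimator. Half-missing genotype tokens collapse to fully missing.
* **Negative θ** is reported as computed; truncation at zero would bias the
  estimator and is left to display code.
* **Monomorphic loci** contribute zero to every component; a dataset with no
  variation at all raises an explicit "no variation" error rather than
  returning 0/0.
* **Confidence intervals** resample loci with replacement (percentile, 95%,
  default 10 000 replicates) because between-locus variation dominates the
  uncertainty of a six-locus panel; a delete-one-locus jackknife with a
  normal-theory interval is provided as an alternative. Bootstrap replicates
  whose resampled loci happen to carry no variation are dropped and counted.
* **GENEPOP dialect**: 2- and 3-digit allele encodings are auto-detected
  from token length and must be consistent within a file; population labels
  default to the id of the last individual in each POP block (the format's
  convention), and readers accept explicit labels for round-tripping
  simulated data.

## Variance components and P_ST (divergence)

The one-way random-intercept model y_ij = μ + u_i + e_ij (u_i ~ N(0, σ²_B),
e_ij ~ N(0, σ²_w)) is fit by REML. The restricted likelihood is profiled in
the single ratio λ = σ²_B/σ²_w: for fixed λ the GLS mean, the residual
quadratic form and both determinant terms are closed-form in per-group
(n_i, ȳ_i, SSW_i), leaving a bounded scalar minimization on log λ over
[−12, 12] (the profile is unimodal for this model) with tolerance 1e-10;
the λ = 0 boundary is always compared against the interior optimum. When
every within-group deviation is exactly zero the profile degenerates
(likelihood unbounded along λ → ∞); the ANOVA moment estimates
(σ̂²_B = MSB/n₀, σ̂²_w = 0) are returned for that case, which agrees with
the balanced-design closed form. For balanced designs with interior
solutions the REML estimates coincide with the ANOVA method-of-moments
estimators, and on general designs they match statsmodels' MixedLM and a
dense-matrix likelihood search to ≤ 1e-6 relative (test suite).

P_ST = cσ²_B / (cσ²_B + 2h²σ²_w) depends on the unknowable c (additive
share of between-population variance) and h² (heritability) only through
r = c/h², so the package evaluates P_ST(r) over a grid, by default
0.05–2.0 in steps of 0.05 — wide enough to bracket critical ratios well
below and above the null hypothesis c = h² (r = 1).

**Bootstrap.** Two resampling units are offered:

* `unit="individuals"` (default): individuals are resampled with
  replacement within their population, preserving the sampling design.
  The resulting interval is *conditional on the realized population
  effects*: it propagates within-population sampling error into the
  variance components but treats the sampled populations' true means as
  fixed. This matches how the ratio is usually reported in P_ST studies.
* `unit="populations"`: a two-stage cluster bootstrap (populations with
  replacement, then individuals within each drawn population). This also
  propagates the between-population sampling of σ²_B and is the variant
  to use when the question is frequentist coverage of a generating
  parameter, e.g. in simulation studies.

Intervals are percentile (95%). Coverage calibration on simulated 20 × 50
designs with σ²_B = σ²_w shows the known behavior of percentile intervals
for right-skewed variance functionals with ~20 clusters: the population-unit
interval covers the generating P_ST in roughly 86–88 of 100 replicates
rather than the nominal 95, with misses one-sided (interval below the
truth); the individual-unit interval, being conditional, is not a coverage
interval for the generating value at all (~40% in the same experiment).
Replicates in which both components collapse to zero are dropped and
counted; more than 20% of them raises an error.

**Critical c/h² ratio.** The inference P_ST > F_ST is robust down to the
ratio where the lower P_ST confidence bound meets the upper F_ST bound. The
implementation takes the largest grid ratio whose lower bound does not
exceed the F_ST bound and refines it by bisection between the bracketing
grid points, re-evaluating P_ST on the stored bootstrap replicates (the
per-replicate P_ST is strictly increasing in r, so the percentile lower
bound is too and bisection is safe). Sentinels mark the two degenerate
outcomes: separation already at the smallest grid ratio, or overlap still
at the largest. With few replicates the lower bound can be non-monotone
across the grid; the last crossing is used and a warning logged.

**Pairwise matrices and Mantel.** Pairwise P_ST refits the variance
components from each population pair alone (not a decomposition of the
global fit). The Mantel statistic is the Pearson correlation of strict
lower triangles; p-values come from jointly permuting the rows/columns of
the second matrix, p = (1 + #{r* ≥ r}) / (n_perm + 1), one-sided greater by
default, with an exact mode that enumerates all n! permutations for small
matrices. Matrices with missing entries are refused rather than imputed.

## Climate summaries (microclimate)

All summaries are restricted to the population's phenology window, stored
as inclusive month-day bounds; start > end means the window wraps 31 Dec
(autumn-breeding lowland populations). Micro-scale, from logger series:

* a day qualifies if its records span ≥ 20 h (configurable); under-covered
  days are excluded and counted;
* tmax = mean daily maximum over the warmest calendar month in the window,
  where "warmest" means highest mean daily maximum and ties go to the
  earlier month; tmin symmetrically via the coldest month; sr = tmax − tmin
  by construction; dr = mean daily range over all qualifying days;
* a month needs ≥ 20 qualifying days to count as complete; with no complete
  month the summary downgrades to all-day means of the daily extrema, with
  a logged warning.

Macro-scale, from monthly tables: a calendar month is included when ≥ 15 of
its days fall in the window; TMAX/TMIN are the extreme monthly values over
included months. Published tables in this field are ambiguous about whether
the seasonal range is the difference of extremes or a mean monthly range,
so both are emitted (`SR` = TMAX − TMIN and `SR_monthly` = mean of monthly
ranges) and only the internal identities are asserted. Duplicate logger
timestamps collapse to their mean; out-of-order rows are sorted; readings
outside −40…60 °C are flagged. A lost logger can be substituted via an
explicit population → donor alias map; nothing is borrowed silently.

## Vulnerability and plasticity (thermal)

The four margins are exact arithmetic on trait means (assayed at the 20 °C
pre-assay acclimation) and climate summaries: WT = CTmax − TMAX,
wt = CTmax − tmax, CT = TMIN − CTmin, ct = tmin − CTmin. Populations
missing either input are omitted with a logged reason.

ARR uses the two-point convention — (mean_high − mean_low)/ΔT between the
extreme treatments (27 vs 6 °C for CTmax; 27 vs 20 °C for CTmin) — rather
than a regression slope, for comparability with the published values; an
OLS-slope variant across all treatments exists as an explicitly
non-standard option. Values are reported to 3 decimals, the field's
convention. CTmin trials at cold acclimation in which the water reached
crystallization before the endpoint only bound the true CTmin from above;
they are treated as censored and removed (no imputation), which restricts
CTmin plasticity analysis to the 20–27 °C treatments by default.

## Inferential battery (stats)

Thin, contract-fixing wrappers over statsmodels/scipy: OLS polynomial
regressions report the overall F with df (degree, n − degree − 1) and
satisfy R² = kF/(kF + df_den) to 1e-9; the ANCOVA reports the partial
(Type II) F for population given body mass; the two-way ANOVA of
acclimation experiments uses sequential (Type I) sums of squares in the
order population, temperature, interaction — matching how such tables are
conventionally printed — and refuses empty design cells; the KS test uses
the asymptotic p-value (sample sizes here make exact small-sample p-values
unnecessary, and the method label records the choice). No multiple-testing
correction is applied across the regression battery, mirroring standard
practice for these descriptive tables.

## Synthetic data (simulate)

One `SimulationConfig` drives four generators; a single global seed is
expanded into per-generator child seeds via `SeedSequence.spawn` at fixed
positions (genotypes 0, traits 1, logger 2, acclimation 3), so adding a
generator never perturbs existing streams, and every output is a pure
function of the seed.

* **Genotypes**: Balding–Nichols island model — population allele-frequency
  vectors drawn from Dirichlet(p_a(1−F)/F) around ancestral frequencies
  (drawn once per locus from a mildly uneven Dirichlet unless supplied),
  genotypes as Hardy–Weinberg draws within populations. F = 0 copies the
  ancestral frequencies exactly. This yields E[F_ST] ≈ F without coalescent
  machinery; at small sample sizes the Weir–Cockerham estimate recovers F
  only in expectation, which is what the tests assert.
* **Traits**: y_ij = grand mean + u_i + e_ij with the configured variances;
  body mass is lognormal and independent of the trait unless a mass-slope
  is set (useful for ANCOVA power experiments).
* **Logger series**: mean + seasonal sinusoid (365 d) + diel sinusoid
  (24 h) + Gaussian noise at a fixed sampling interval.
* **Acclimation**: tolerance = population intercept + ARR·(T_acc − 20) +
  noise, with per-population true ARRs and configurable, possibly
  unbalanced group sizes.

Defaults mirror the study system the package targets: 11 populations,
16 individuals per population per assay, 6 loci × 8 alleles, target F_ST
0.066, CTmax-like variances (σ²_B = 0.06, σ²_w = 0.16, grand mean 36.8 °C —
consistent with assay standard errors of ~0.1 °C at n = 16 and an
among-population mean range near 1 °C), 30-min logger sampling, and
acclimation treatments at 6/13/20/27 °C with ARR 0.1.

What the generators do **not** emulate: family structure within populations
(field samples are mixtures of a few clutches; no family effects are
simulated, so within-population correlations are absent), microsatellite
mutation processes (no stepwise-mutation allele-size structure), spatially
explicit gene flow, logger gaps/outages, and trait–environment covariance.
Passing tests therefore demonstrate estimator correctness and calibration
under the idealized design, not robustness to those real-data features.

## Pipeline

Stages run in the order climate → vulnerability → F_ST → P_ST → critical
ratio → Mantel → battery → plasticity, communicate only through serialized
CSV/JSON outputs, skip (and record) when inputs are absent, and abort with
a manifest of completed stages on error. All seeds are explicit in the
config; per-stage child seeds derive from the run seed by a fixed scheme.
Test-suite and pipeline problem sizes (e.g. 100-replicate recovery panels,
500-replicate bootstrap calibrations, 20 × 50 coverage designs) were chosen
as the smallest designs at which the asserted tolerances are comfortably
inside sampling noise.

## Known limitations

* P_ST remains a surrogate for Q_ST: non-additive variance, maternal and
  environmental effects can distort it, which is exactly why the critical
  c/h² ratio is reported instead of a single test.
* Percentile bootstrap intervals for variance-ratio functionals undercover
  with ~20 clusters (see above); a BCa option would narrow but not close
  the gap at these design sizes.
* Marker QC (null-allele screening, HWE/LD exact tests) is upstream of this
  package: it consumes a cleaned marker panel.
* The KS p-value is asymptotic; at n ≈ 11 per sample it is indicative, not
  exact.
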