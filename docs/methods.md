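# Methods

`morphoxfer` implements a propensity-matched, model-transfer analysis of
regional brain morphometry for unbalanced clinical cohorts, with a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes. This note documents the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic experiments do and
do not demonstrate.

## The analysis model

**Propensity matching.** For two groups defined by a binary outcome *y*
(diagnosis, variant carriership, or SAA status), a logistic regression
estimates PS = P(y = 1 | C) from background covariates C only — age (years),
sex (female = 0, male = 1 in this stage), acquisition site (indicator-coded),
and, where the comparison involves two patient groups, disease duration
(years). Morphometry columns are refused as covariates by construction.
Pairs are formed by solving the minimum-cost one-to-one assignment
(Hungarian algorithm via `scipy.optimize.linear_sum_assignment`) on the
matrix of absolute PS differences. A caliper excludes insufficiently close
pairs: entries beyond it are priced at a sentinel cost
(n_A + n_B) × (max gap + 1), and any pair assigned at sentinel cost is
dropped, so participants without a close counterpart are left unmatched.

*Caliper default:* 0.2 × SD of the logit of the pooled scores, applied on
the logit scale — the standard convention in the matching literature. The
value and scale are always recorded in outputs. If the PS carries no signal
at all (zero logit variance), the caliper is disabled rather than set to
zero, since identical scores leave nothing to constrain.

*Determinism:* costs are rounded at 1e-12 before solving and participants
are processed in id order, so the matching is invariant to row order.

*Separation:* small subgroups with site indicators occasionally separate; the
maximum-likelihood fit then falls back to a ridge-penalized fit (penalty
1e-4) with a logged warning.

*Balance:* standardized mean differences (|Δmean| / pooled SD; proportion
variance p(1−p) for binary covariates) are reported per covariate before and
after matching.

**Regional atrophy models.** On the matched reference sample (sporadic PD
vs healthy controls), each of the 82 regions — 68 Desikan-Killiany cortical
thickness parcels (mm) and 14 Harvard-Oxford subcortical volume parcels
(mm³) — gets its own OLS model:

    Y = b0 + b1·diagnosis + b2·age + b3·sex + b4·site (+ b5·TIV)

TIV enters subcortical volume models only. Sex is coded male = 0, female = 1
in this stage (the two stages deliberately use opposite conventions; the
diagnosis coefficient is unaffected by either). Age is centered at the
reference-sample mean, which shifts only the intercept. An explicit
intercept with reference-level site coding is equivalent to a no-intercept
parameterization with a full set of site indicators, and keeps the
"in-sample mean residual = 0" property testable.

Outcomes are z-scored per region by default, using the reference-sample
mean/SD, which are stored in the model set; native-units mode is available.
Z-scoring makes b1 scale-free, in line with diagnosis effects of magnitude
≈ 0.3 being interpretable as standardized effects, and lets thickness and
volume coefficients share one scale.

**Model transfer.** The fitted model set is applied with frozen coefficients
to matched data-poor subgroups. Predictions use each participant's observed
diagnosis status (1 for both sides of the LRRK2 PD vs sPD contrast, 0 for
both sides of NMC vs HC, observed status for the SAA contrast) so that a
non-diagnosis contrast is a pure non-diagnosis contrast. Measured values are
standardized with the training-sample parameters carried inside the model
set — the transfer never peeks at target-group statistics. The prediction
difference is measured − predicted, so positive values mean structure is
better preserved than the reference PD atrophy model expects. Site levels
unseen at training raise an error by default (a map-to-reference option
exists, with a warning).

Differences are averaged per region within subgroup; subgroups are compared
by a two-sided t-test whose unit of analysis is the 82 per-region subgroup
means. The default family is Welch's two-sample test; a paired option pairs
regions across subgroups. The paired variant cancels the model-estimation
error shared by the two arms and is nominally calibrated; the two-sample
default is mildly conservative for exactly that reason (see Calibration
below).

**Spatial comparison.** Two brain maps are compared by Pearson correlation
with a spin-permutation null: random 3-D rotations (`special_ortho_group`)
are applied to the cortical parcel centroids of a designated map, with the
x-mirrored rotation applied to the opposite hemisphere, and parcel values
are reassigned by nearest rotated centroid. Only the 68 cortical parcels
participate — subcortical structures have no spherical embedding — with a
uniform-permutation option that covers all 82. The p-value is two-sided on
|r|: p = (1 + #{|r_null| ≥ |r_obs|}) / (n_perm + 1), bounded below by
1/(n_perm + 1). Nearest-centroid reassignment is not always bijective; the
mean number of duplicated assignments per rotation is logged in the result.

**Clinical and genetic associations.** The structural quantity correlated
with clinical scores is the model-predicted morphometry (configurable to
measured values or prediction differences). Global analyses correlate the
per-participant mean over regions with UPDRS III, MoCA, and PRS; PRS uses a
partial correlation controlling the first 10 genetic principal components
(residualize both variables on the PCs plus intercept, correlate the
residuals, p from t with n − 2 − k df). Benjamini-Hochberg FDR is applied
within families: the 3 global tests, and the full 82 × 3 regional family.

## The synthetic cohort generator

The generator is the package's test bed and defines its study conditions.
Four groups mirror a PPMI-like cohort: sPD n = 293 (age 63.3 ± 9.5, 181
male, duration 2.2 ± 1.9 y), LRRK2 PD n = 77 (65.0 ± 8.7, 44 male,
3.2 ± 2.2 y), HC n = 139 (61.1 ± 11.7, 92 male), LRRK2 NMC n = 94
(62.0 ± 6.9, 40 male). Regional values are

    value = baseline_mean + scale · (age_slope·(age − 60) + site_offset
            + pd·effect·attenuation + saa⁺·saa_scale·effect
            + tiv_coupling·tiv_z [subcortical] + noise)

with `scale` the per-region baseline SD (effects are specified in SD units
by default; a native-units switch exists).

Defaults and rationale:

- **Diagnosis effects**: drawn once per pattern from Uniform(−0.4, 0) SD,
  echoing the magnitude range of the strongest standardized atrophy
  coefficients (≈ −0.3) reported for PD.
- **Noise SD**: 1 SD per region — the canonical unit for standardized
  effects.
- **LRRK2 attenuation**: 0.5 — LRRK2 PD expresses the PD pattern at half
  strength, a concrete instantiation of "milder atrophy with the same
  covariate structure".
- **SAA effect scale**: 1.0 — SAA positivity (a proxy for Lewy pathology,
  the process presumed to drive the atrophy pattern) adds one extra unit of
  the per-region effect profile on top of any diagnosis effect. SAA rates
  per group default to 0.92 (sPD), 0.67 (LRRK2 PD), 0.05 (HC), 0.10 (NMC),
  with 25% of statuses missing, reproducing the cohort's composition
  (roughly 296 positives among 603, two-thirds positivity in LRRK2 PD).
  Because the reference sPD sample is predominantly SAA-positive, the
  fitted diagnosis coefficients absorb most of the SAA effect, so the SAA
  contrast measures the *residual* effect beyond what the reference model
  already encodes — an unavoidable property of any cohort in which nearly
  all sporadic patients carry the pathology marker.
- **Sites**: 5 sites with additive region-constant Gaussian offsets
  (SD 0.1): the simplest structure that makes site a genuine confounder
  worth matching away. Site offsets are properties of scanners, so all
  subgroups of one cohort share them.
- **Age slope**: −0.02 SD/yr, in the range reported for adult cortical
  thinning.
- **TIV**: 1.45e6 ± 1.5e5 mm³, coupled to subcortical volumes at 0.3 SD per
  TIV SD.
- **Clinical coupling**: MoCA = 26.5 + 5·(mean deviation) + N(0, 2) clipped
  to [0, 30]; UPDRS III = (21 if PD else 2) − 10·(mean deviation) + N(0, 8)
  floored at 0, where "mean deviation" is the participant's mean
  disease/SAA/age-driven structural deviation in SD units. Signs follow the
  observed directionality: preserved structure goes with better cognition
  and milder motor signs.
- **PRS**: standard normal plus +0.5 for LRRK2 carriers and +0.3 for PD;
  10 genetic PCs are standard normal with identity covariance.

`balanced_config` builds cohorts in which all groups share one demographic
distribution — the state matching is meant to produce — so repeated
simulations can run at fixed post-matching sizes (104/arm reference,
19/42/23 per side for the three transfer contrasts — the matched counts
such cohorts realistically yield) without re-running the matching inside
every repetition. The
matching stage itself is exercised separately on deliberately imbalanced
cohorts.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring parcels (region noise is independent), scanner-specific
region-dependent biases, non-Gaussian morphometry tails, medication or
comorbidity effects, and longitudinal change. Passing tests therefore show
that the machinery recovers the structure it assumes; they do not certify
performance on real multi-site MRI.

## Calibration and power characteristics

Simulation experiments in the test suite characterize the pipeline at the
published sample scales (all fully determined by fixed seeds):

- The assignment solver and regional OLS match exhaustive / normal-equations
  oracles exactly; partial correlation and BH-FDR match their independent
  oracles to 1e-10/1e-12.
- Diagnosis-coefficient recovery at 104/arm: mean absolute error ≈ 0.11 SD
  across 82 regions, 95% CI coverage ≈ 95%.
- Transfer test, attenuation 0.5 at 19/side: mean preservation is positive
  in ~100% of repetitions; the two-sample region-level test rejects in
  ≈ 75-78% — consistent with its theoretical noncentrality (signal
  0.5 × 0.2 SD against region-mean noise 1/√19), so claims of higher power
  at this scale would be optimistic.
- Null arms at 42/side reject at ≈ 0.018-0.02 at nominal α = 0.05: the two
  arms share the frozen model's estimation error (variance ≈ σ²/104 per
  region), which inflates both sample variances but cancels in the mean
  difference, making the two-sample default conservative by a factor
  ≈ √(1 + 42/104) on the t scale. The paired family does not have this
  conservatism.
- Post-matching SMD(age) in a deliberately confounded scenario (age +4 y,
  sites 2:1, 150/arm) is ≈ 0.05 on average but exceeds 0.1 in ≈ 10% of
  seeds at any caliper width: a one-dimensional PS distance allows pairs to
  trade age against sex/site within the caliper, a known property of PS
  matching rather than an implementation defect.
- The spin test is calibrated on white-noise maps (type-I ≈ 0.05) and its p
  attains exactly 1/(n_perm + 1) on identical maps.

## Reproducibility

A single top-level seed fans out to per-stage seeds via spawned
`numpy.random.SeedSequence` children (order: cohort, spin); every stage is
deterministic given its seed, and `run-all` produces byte-identical
manifests (modulo timestamp) on repeated runs. Manifests embed a hash of
the generating configuration, the caliper value and scale, matched ids, and
all test statistics.
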