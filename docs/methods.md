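# Methods

## Model and estimand

The package models the expected proportional change in a cognitive score
over a 3–4-year follow-up as a sigmoid Emax (Hill) function of baseline
age,

    E(a) = E0 + Emax * a^h / (ET50^h + a^h),

with E0 the stable pre-decline change level (dimensionless proportional
change), Emax the asymptotic additional age effect (negative for
decline), ET50 the age of half-maximal effect (years) and h > 0 the Hill
coefficient. The scientific estimand is EC_p = ET50 * (p/(100-p))^(1/h),
the age at which p% of the maximum age effect has accrued; EC_1 is
interpreted as the earliest age of detectable change and is reported as
a 5-year age band, (floor(EC_1), floor(EC_1)+4). EC_p values outside the
observed age range are extrapolations of the fitted curve and are
flagged as such.

Assumptions worth keeping in view: age is the sole predictor (no
covariates); change is summarized per participant by a single
two-timepoint difference; the age trend is monotone; and group
membership (prospective AD converter vs. healthy control) is known from
follow-up, so the converters' curve describes people who will go on to
diagnosis, not a screening rule.

## Pipeline conventions

- **Eligibility.** Follow-up window closed at both ends, [3, 4] years —
  the literal reading of "at least 3 to a maximum of 4". Prevalent
  baseline dementia excluded via a `baseline_dementia` marker column.
- **Change scores.** Proportional change is (T2 - baseline)/baseline,
  multiplied by -1 for instruments where higher scores are worse (Trail
  Making B), so decline is negative everywhere and one Emax code path
  serves all tests. Zero baselines (undefined ratio) are dropped and
  counted; denominators other than the baseline score are configurable
  at the call site but not defaulted.
- **Banding.** Moving 5-year windows advance in 1-year steps from 65;
  membership is half-open by baseline age, [start, start+5), while the
  printed label is start–(start+4). Outlier status is decided once per
  participant using Tukey fences (k = 1.5) within the participant's
  *static* band (65–69, 70–74, …) and then applied to every moving
  window containing them. Quartiles use the linear-interpolation rule
  (numpy's default) — fences on tiny bands are sensitive to this
  choice, so it is fixed and documented. Windows with fewer than four
  post-fence observations are excluded from fitting (the paucity check
  counts analyzable observations; a flag restores the pre-fence count).
  The series ends at the last window containing any observation. The
  "clinical anomaly" exclusion is an explicit analyst-supplied id list,
  never an automatic rule.
- **Fit.** Bounded least squares (scipy trf) on the band series, band
  age = window midpoint (start + 2; band start available by config).
  Multi-start over ET50 ∈ {55, 65, 75, 85, 95} × h ∈ {1, 4, 8, 16, 32},
  E0/Emax started from the series extremes; bounds ET50 ∈ (20, 130),
  h ∈ (0.1, 50), |Emax| ≤ 2, E0 within the data range ± its span; cost
  tolerance 1e-10. Residuals are weighted by sqrt(n_obs) by default:
  band means are averages, so their sampling variance scales as 1/n, and
  unweighted fits let the handful-sized oldest bands drive the fit to a
  bound on realistic cohorts (in recovery experiments, weighting removed
  all such spurious bound-pinning). `FitConfig(weight_by_n=False)`
  restores plain least squares.
- **Convergence.** A fit is reported converged only when the optimizer
  succeeds and no shape parameter (ET50, h, Emax) sits at a bound.
  Bound-pinning is the canonical failure of Hill models on step-like or
  flat series (h → ∞, or Emax unidentified when the transition lies
  beyond the data), and non-convergence is a first-class, table-rendered
  outcome ("–"), never an exception.
- **Power analysis.** Raw changes in the chosen band are rescaled
  per participant by duration/followup (the linear choice; nothing in
  the two-timepoint design identifies a better one), giving the
  placebo-arm mean and sample SD. Treatment mean = control mean ×
  (1 − efficacy). Cohen's d = (control − treatment)/pooled SD — signed
  so that a beneficial treatment on decline-negative data yields
  negative d, matching the planning-table convention; only |d| enters
  the power computation. The minimal per-group n is found exactly via
  the noncentral t distribution (df = 2n − 2, ncp = |d|·sqrt(n/2)),
  one-sided α = 0.05 and 80% power by default, by exponential bracketing
  plus integer bisection. d is carried at full precision through the
  chain; `round_d=True` instead feeds the two-decimal d, for reproducing
  calculations whose only record is a printed effect size. With the
  printed verbal-fluency inputs (−4.13, 8.03) the chain returns totals
  of 766 and 168 at 35%/75% efficacy; the corresponding published totals
  are 768 and 168 — the 35% figure evidently used an effect size carried
  at higher precision than the printed means can supply, so agreement
  there is to ~0.3%, not exact. The analogous global-cognition (MMSE)
  totals are reproducible in neither mode from printed inputs and are
  not asserted anywhere.

## Synthetic cohorts

The generator emulates a two-timepoint prospective cohort: baseline ages
from normals truncated to [65, 90] (location solved numerically so the
*truncated* means hit the configured group targets, 74.95/72.56 years;
naive targeting would overshoot by up to ~0.8 years), follow-up uniform
on [3, 4] years, group sizes 101/1392, sex and education drawn from the
configured group frequencies, and AD diagnosis ages normal(82.41, 5.56)
truncated to at least the T2 age. Per instrument, T2 score = baseline ×
(1 + s·(μ(a) + ε)) clamped to the instrument range, where μ(a) is the
group's generating Emax curve, ε ~ N(0, noise_sd) on the
proportional-change scale (the scale the analysis models, hence the most
directly controllable error structure), and s = ±1 encodes score
direction. Clamped records are kept: floor/ceiling effects reach the
analysis as they would in real data.

Default generating curves encode the qualitative study picture — AD
converters decline earlier and more steeply than controls; verbal
fluency departs from stability decades before the observed window (EC_1
extrapolating into the 40s); global cognition in AD converters near
EC_1 ≈ 69 (ET50 = 82, h = 26, Emax = −0.45); control curves transition
at or beyond the edge of the observed range. Defaults for noise_sd
(0.08 MMSE, 0.15 Isaacs, 0.30 TMT-B) reflect typical two-timepoint
test-retest variability relative to baseline scores.

What the generator does *not* emulate: within-person correlation beyond
the multiplicative construction (real test-retest correlation is not
identified by anything modeled here), practice effects, dropout or
mortality, more than two timepoints, and covariate structure (APOE,
education effects on decline). Passing tests therefore demonstrate that
the estimator recovers the assumed data-generating process at realistic
sizes and noise — not that real cohorts satisfy those assumptions.

## Parameter recovery benchmark

Twenty cohorts of n = 1400 (the healthy-control sample size) are drawn
from the default AD global-cognition curve with noise_sd = 0.08, run
through the full pipeline, and the fitted EC_1 band and ET50 are
compared with truth (acceptance: ≥ 80% of replicates within ±1 band;
median |ET50 error| < 2 years; observed ≈ 90% and ≈ 0.5–1 year). The
benchmark curve deliberately has its transition *inside* the densely
observed 65–90 window: when ET50 lies at or beyond the edge of the data
(as the control curves do), Emax, ET50 and h are jointly unidentifiable
from band means, recovery of individual parameters is not meaningful,
and the correct behavior — exercised elsewhere in the suite — is a
non-converged fit.

## Degenerate inputs and tie-breaks

Constant series fit as Emax ≈ 0 (or report non-convergence; both are
legal, never an exception). Fewer than four usable bands raise an
insufficient-data error (four free parameters). Ties at Tukey fences
are kept (strict inequality flags). Identical band-series inputs in any
order, with any number of excluded bands appended, give identical fits.
All randomness flows from a single integer seed (per-stage sub-seeds are
derived by CRC-mixing, keeping them below 2^31), and identical
configuration + seed reproduces outputs byte for byte.

## Known limitations

EC_1 for shallow curves (small |Emax| relative to noise) is poorly
determined, and its band label can move by several years between seeds;
the ±1-band recovery holds in the benchmark regime, not universally.
The moving-average bands induce serial correlation between adjacent
band means that plain least squares ignores — standard errors on fitted
parameters are therefore not reported (and no EC_p uncertainty
intervals are offered). Sample-size results assume the trial's change
scores are approximately normal with equal variances across arms.
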