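# emaxtraj

Sigmoid Emax modeling of age-banded cognitive decline, with trial
sample-size planning.

## The problem

Randomized trials of disease-modifying therapies for Alzheimer's disease
(AD) typically enroll participants across very wide age ranges, even
though cognitive decline begins at different ages on different cognitive
instruments — and decades before diagnosis on some of them. This package
implements a trajectory-modeling approach that locates the **earliest age
band of detectable decline** for a cognitive test, separately in
prospective AD converters and in healthy controls, and then converts the
observed decline in a chosen age band into the effect sizes and sample
sizes a hypothetical prevention trial would need. It is written for
biostatisticians and epidemiologists planning cognitive endpoints for
AD prevention studies.

## The model

Treat baseline age $a$ as the "dose" and the mean proportional change in
a cognitive score over a 3–4-year follow-up as the "effect". The sigmoid
Emax (Hill) model

$$E(a) = E_0 + E_{max}\frac{a^h}{ET_{50}^h + a^h}$$

encodes a stable pre-decline level ($E_0$), a transition beginning at
some age, and an eventual asymptote ($E_0 + E_{max}$; $E_{max} < 0$ for
decline). $ET_{50}$ is the age of half-maximal effect and $h$ the Hill
coefficient controlling steepness. The age at which $p\%$ of the maximum
age effect is reached inverts in closed form:

$$EC_p = ET_{50}\left(\frac{p}{100-p}\right)^{1/h},$$

and $EC_1$ — one percent of the maximum effect — is read as the earliest
age of detectable change, reported as a 5-year age band.

The pipeline:

1. **Eligibility** — keep participants whose follow-up fell 3–4 years
   (inclusive) after baseline; exclude prevalent baseline dementia.
2. **Change scores** — raw change ($T_2 -$ baseline, native scale) and
   proportional change $((T_2 - \text{baseline})/\text{baseline})$,
   sign-normalized so decline is negative on every instrument (timed
   tests are flipped).
3. **Age bands** — mean proportional change in 5-year moving windows of
   baseline age (65–69, 66–70, …). Tukey-fence outliers
   ($>1.5\times$ IQR, judged within the participant's static 5-year
   band) are excluded, and windows with fewer than four remaining
   observations are dropped from fitting.
4. **Emax fit** — bounded multi-start least squares of $E(a)$ to the
   band series (n-weighted by default); non-convergence is a reported
   outcome, not an error.
5. **EC_p inversion** — closed-form $EC_1$, $EC_5$, $EC_{10}$ ages and
   band labels.
6. **Power analysis** — raw changes in a chosen band, rescaled to the
   trial duration, give the placebo-arm mean and SD; a treatment of
   efficacy $f$ shrinks the mean by $1-f$; Cohen's $d$ feeds an exact
   noncentral-$t$ minimal-sample-size search for a two-sample $t$-test.

A synthetic cohort generator (101 AD converters, 1392 controls by
default, with MMSE, Isaacs Set Test and Trail Making Test B analogues)
makes every stage testable end to end, including parameter recovery
against known generating curves.

## Worked example

Fit the global-cognition instrument in a simulated study-sized cohort:

```python
from emaxtraj import (compute_changes, filter_eligible, fit_emax,
                      fit_report, generate_cohort, summarize_moving_bands)
from emaxtraj.synthetic import default_cohort_spec

spec = default_cohort_spec(seed=1)
eligible = filter_eligible(generate_cohort(spec))
test = next(t for t in spec.tests if t.test_name == "mmse")
fits = {}
for group in ("AD", "control"):
    changes = compute_changes([r for r in eligible if r.group == group], test)
    fits[(group, "mmse")] = fit_emax(summarize_moving_bands(changes))
print(fit_report(fits, (1, 5, 10)).to_string(index=False))
```

```
  group test  EC_1  EC_5 EC_10
     AD mmse 71–75 74–78 75–79
control mmse     –     –     –
```

The AD converters' curve converges and places the earliest detectable
MMSE decline in the 71–75 band (the generating curve's true $EC_1$ is
68.7 years; with only 101 converters the band estimate is noisy). The
healthy controls' series is nearly flat across the observed 65–90 age
range — their generating curve declines much later — so the fit does not
converge and every EC column renders as "–", exactly how weakly
identified trajectories should be reported.

The same workflow from the shell, ending in a trial-planning table for
the verbal-fluency test in the 77–81 band:

```bash
emaxtraj simulate --n-ad 101 --n-control 1392 --seed 1 -o cohort.csv
emaxtraj prep -i cohort.csv --test isaacs --group AD -o changes.csv
emaxtraj power -i changes.csv --band 77-81
```

```
  test  band  control_mean_change  pooled_sd  treatment_mean_35%  d_35%  n_total_35%  treatment_mean_75%  d_75%  n_total_75%
isaacs 77–81                -3.22       3.14               -2.09  -0.36          194               -0.81  -0.77           44
```

Reading the row: simulated AD converters aged 77–81 lose 3.22 points
over a 2-year horizon (SD 3.14). A treatment removing 35% of that
decline gives $d = -0.36$, needing 194 participants in total for 80%
power (one-sided $\alpha = 0.05$); at 75% efficacy, 44 suffice.

`emaxtraj run -c config.yaml` executes the whole pipeline (simulation or
a cohort file, all tests × groups, EC_p and power reports, plots, and a
manifest reconciling every exclusion) reproducibly under a single seed.

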