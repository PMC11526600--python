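# Methods

This note records the statistical model behind `toptrial`, the defaults
and the reasoning for every choice that the published design descriptions
leave open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Outcome model

Each patient carries two latent binary outcomes: response within a
`T_eff = 180` day window and unacceptable toxicity within a `T_tox = 42`
day window. A scenario specifies the marginals `(p_eff, p_tox)` and the
Pearson correlation `R` of the two indicators. For Bernoulli margins `R`
is feasible only within

```
R_min = (max(0, p_eff + p_tox - 1) - p_eff*p_tox) / s,
R_max = (min(p_eff, p_tox)         - p_eff*p_tox) / s,
s     = sqrt(p_eff(1-p_eff) p_tox(1-p_tox)),
```

and the four multinomial cells follow from
`pi_11 = p_eff*p_tox + R*s` by marginal subtraction. The named preset
`pos1` is `R_max/3`, computed from the exact bound and rounded only for
display; the calibration hypotheses H0 = (0.15, 0.30, R=0.21) and
H1 = (0.30, 0.20, R=0.26) equal this preset rounded to two decimals.
A six-point evenly spaced grid from `R_min` to `R_max` is provided for
correlation sweeps; only the `pos1` point is anchored to a published cell
table, the grid spacing is this package's choice.

## Patient streams

Accrual is a homogeneous Poisson process (exponential gaps, mean 6 days,
i.e. 5 patients/month; a deterministic-grid mode exists for exact tests).
The accrual law is not stated beyond its mean; a Poisson process is the
standard assumption for trial simulators and the mode is configurable so
the sensitivity is testable. MET-amplification status is an independent
Bernoulli(0.10) per patient — the expected split of 90 patients is 81
MET-negative / 9 MET-positive, but the realised count varies; the final
efficacy analysis uses the MET-negative patients actually available (at
most 81), with the threshold `C_n` evaluated at that realised `n`.
Event times are uniform on `(0, window]` for patients with an event;
non-events are ascertained only when the window closes. No dropout and no
competing risks are modelled.

## Posterior machinery

All rules are conjugate. The joint model is Dirichlet-multinomial over the
four cells; because every decision rule uses a *marginal* tail, the
aggregation property reduces each test to a Beta tail on grouped
pseudo-counts, which is how the engine evaluates them. Priors: the BOP2
convention for the optimal-phase-II family (Dirichlet matching the H0
cells with total effective sample size 1, hence efficacy marginal
Beta(0.15, 0.85) and toxicity marginal Beta(0.30, 0.70)), and a uniform
Beta(1, 1) for the stand-alone PP toxicity monitor. Pending patients enter
the efficacy likelihood with weight `w = follow-up / T_eff` under the
uniform event-time assumption: a patient with an observed response
contributes (1, 1), a completed window without response (0, 1), a pending
patient (0, w). Fractional pseudo-counts plug directly into the Beta
update; this closed-form approximation is what makes time-to-event
monitoring cheap to calibrate.

### Conventions adopted where the rules are under-specified

Two operational details materially change the operating characteristics
and are not pinned down by the design descriptions. The package adopts the
following, chosen because they reproduce the published planning numbers
(the 49%/95% early-stopping probabilities, the Simon and BOP2 comparison
values) and are statistically defensible:

1. **Binary toxicity ascertainment.** At a PP look the analysis set is the
   patients whose 42-day window is complete; a determined event inside an
   open window is *not* counted early. Counting early-determined events
   while their event-free contemporaries remain invisible biases the
   interim rate upward and roughly triples early toxicity stopping under a
   20% true rate. The stop count is re-derived from the posterior at the
   ascertained `m`, not read off a table indexed by the look size.

2. **Information-indexed interim thresholds.** At a weighted
   (time-to-event) interim the threshold is `C_m` with `m` the effective
   (weighted) sample size, not `C_n` at the enrolled count. With `C_n` the
   interim would spend its stringency as if full information were in hand
   while the weighted posterior still sits near the prior; under the
   alternative this stops ~9% of trials at the first look and depresses
   every power value ~6 points below the published ones. Indexing the
   spending function by information fraction is the standard group-
   sequential principle and restores the published behaviour to within
   ~2 points.

One published value resists both conventions: the combined TOP+PP power
under H1 (94.25%). The toxicity rule that produces the published 49%/95%
stopping probabilities at 30%/40% toxicity necessarily removes ~6% of
trials at 20% toxicity under these looks and this accrual (verified by
sweeping ascertainment conventions and priors), which caps the combined
power near 90%; the published BOP2+PP value (87.99%), with identical
boundaries and more mature toxicity data, corroborates that level. The
simulator reports ~87.5% and the discrepancy is documented rather than
patched.

## The five designs

Shared structure: efficacy looks at 30 and 81 evaluable (MET-negative)
patients with `N = 81` inside `C_n`; binding rules throughout; total
enrollment capped at 90.

| kind | efficacy | toxicity | lambda/gamma |
|------|----------|----------|--------------|
| `top_eff` | TOP weighted interim, complete-data final | none | 0.92 / 0.97 |
| `top_pp` | TOP as above | PP at 5..90 (all patients) | 0.865 / 0.91 |
| `simon_pp` | Simon r1=4/30, r=18/81 (exact search) | PP at 5..90 | — |
| `bop_pp` | complete-data boundaries, accrual suspended | PP at 5..90 | 0.865 / 0.91 |
| `top_joint` | TOP interim + final | `Pr(p_tox>0.30|D)>C_n` at 5..70, 81 | 0.69 / 0.98 |
| `itop_joint` | as `top_joint` | same + informative prior | 0.69 / 0.98 |

Details and decisions:

- **Final analysis.** Every design concludes on complete data once the
  last required window closes. A positive trial must pass the final
  futility rule (Simon: `X > r`) *and*, for designs with a toxicity rule,
  a final application of that rule to the complete toxicity data of all
  enrolled patients. Re-applying the toxicity rule at the end was an open
  point; a positive conclusion claims acceptable toxicity, so it is
  checked against all the toxicity information collected.
- **Suspension.** Binary designs (`simon_pp`, `bop_pp`) suspend accrual at
  each efficacy interim until every enrolled patient's windows are
  complete (the analysis day is the newest arrival + 180 d); accrual then
  resumes with fresh gaps. Toxicity looks remain tied to enrollment
  counts, so no looks fire during a suspension.
- **Joint designs.** Toxicity looks count MET-negative patients and use
  fractionally weighted toxicity data (`w = follow-up / 42` for pending
  patients) with the same `C` family and `N = 81`; the look at 81 is the
  final analysis. `top_joint` models the simpler homogeneous population
  (no MET-positive patients, cap 81). `itop_joint` keeps the 90-patient
  mixed population and, at every toxicity evaluation, adds the completed
  MET-positive toxicity observations `(x_pos, n_pos - x_pos)` to the
  toxicity prior — toxicity is assumed homogeneous across MET status.
- **Simon calibration.** Exhaustive search over `(r1, r)` with stages
  fixed at 30/81: exact binomial type I error <= 0.05 and power >= 0.90,
  minimising `EN(p0)`, ties to smaller alpha then larger power. The
  selected design is r1=4, r=18 (alpha 2.7%, power 90.7%, EN 54.3).
  The constraint pair is this package's default; only the minimised
  criterion is published.
- **Duration** runs from first enrollment to the decision day: the
  triggering look's analysis day for an early stop, the completion of the
  last required observation window otherwise. "Early stopping" means any
  binding stop before the final efficacy analysis.

## Calibration

`calibrate_lambda_gamma` grid-searches `(lambda, gamma)` by simulation
under the H0/H1 pair with common random numbers across grid points, keeps
points with estimated type I error under the cap (0.05 for complete
designs; 0.10 was the published choice for the stand-alone futility rule)
and maximises power, breaking ties toward larger lambda then gamma. Note
that the type I error is non-increasing in lambda at fixed gamma (larger
lambda lowers every threshold `C_n`, so stopping can only increase); the
default grid resolution (0.005) is a package choice.

## Monte Carlo conventions

One root seed per run; each replicate draws its patient stream from a
spawned child seed, so a given seed reproduces streams exactly and designs
compared under the same seed see common random numbers. Probabilities are
reported with binomial standard errors. The published comparison used
10,000 replicates of 90-patient trials and the acceptance script does the
same (~35 s on one CPU for all twelve quantities); unit tests use a few
hundred to a few thousand replicates, sized so that 3-sigma Monte Carlo
bands keep them deterministic under their fixed seeds.

## What the generator does not emulate

Uniform event times are a stylised stand-in for real response/toxicity
kinetics; there is no dropout, no death as a competing risk, no
batch-reporting delay of assessments, and MET prevalence is exactly 10%
Bernoulli. Passing tests therefore certify the decision rules and their
frequentist behaviour under the stated generative model, not performance
on any real trial population. Degenerate scenarios (probabilities 0 or 1)
force `R = 0` and are exercised in tests; thresholds at the final look
reduce to `1 - lambda`; weighted counts of zero skip an interim (no
information, no decision).
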