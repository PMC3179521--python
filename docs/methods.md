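# Methods

## Model overview

`oasim` is an individual-level discrete-event simulation (DES) of lifetime
osteoarthritis (OA) in a closed cohort of Australians aged 40+ with at least
one hip or knee at grade-2 symptomatic OA or worse.  Each person carries two
joints (left/right of one site; persons with both hip and knee OA are out of
scope), each with its own severity, implant status and event stream.  Two
arms are simulated for every person under common random numbers: an
intervention arm in which severe symptomatic joints may receive total joint
replacement (and revisions after implant failure, repeatedly, for life), and
a comparator arm of continued conservative management only.  The cohort is
followed until extinct.

Outcomes are discounted DALYs averted, incremental discounted costs under a
scenario grid, and their ratio (ICER), with 95% uncertainty intervals from a
probabilistic sensitivity analysis (PSA).

## Disease and event model

OA severity follows a forward-only ladder
`none → grade-2 radiological → grade-2 symptomatic → grade-3/4 asymptomatic
→ grade-3/4 symptomatic`, with exponential waiting times per rung
(annual rates per site).  The published grade taxonomy distinguishes
symptomatic/asymptomatic branches; we collapse them onto this single ordered
ladder, which preserves the states and their disability weights while
keeping every transition a single rate.

Only grade-3/4 symptomatic joints are eligible for surgery; the time to the
decision is exponential with the annual surgical uptake rate.  Each
operation (primary or revision):

1. kills the patient with probability `surgical_death_prob` (Bernoulli);
2. otherwise draws a complication Bernoulli (`+Cscc` vs `−Cscc` cost class);
3. sets the joint's disability weight to `DW_pre · (1 − Effect)`;
4. draws an implant time-to-failure from the site's Weibull mixture.

A failed implant enters a failed-implant state (disability weight a
parameter, default worse than untreated severe OA) and is revised
immediately — no waiting-list dynamics.  Revisions repeat for life (capped
at 16 per joint, which is unreachable at realistic implant survival).
Fatal operations are costed at the `+Cscc` class of the attempted operation.

Background mortality is a piecewise-constant hazard over 5-year age bands
(sex-specific), multiplied by the OA mortality relative risk of 1.1 while
the person has at least one joint with untreated symptomatic-or-worse OA.
When the last such joint receives a functioning implant the multiplier
reverts to 1.0.  Whether the excess mortality should revert after
successful surgery is not empirically settled; we adopt reversion because
it is the only mechanism by which surgery
can extend life (and hence generate the "unrelated costs in extended
life-years" scenario).  A single Exp(1) threshold per person is spent
against the accumulated hazard integral, so the death time responds
deterministically — and continuously — to multiplier changes, preserving
common random numbers across arms.

Event ties are broken in the order death > operation > failure >
progression (death dominates, conservatively).

### Randomness and the two joints

Each person's entire uniform budget is pre-drawn once and shared by both
arms (common random numbers), so the arm difference isolates the
intervention.  The two joints' time-to-event uniforms (progression,
surgery-decision, implant failure) can be correlated via a Gaussian copula
with normal-score correlation ρ ∈ [−0.99, 0.99] (rank correlation
(6/π)·arcsin(ρ/2)); surgical-death and complication draws stay independent.
Per-person substreams are keyed by (seed, person id), so results do not
depend on cohort order.

## Implant survival

Implant failures arise from short-term causes (observed in registry data
over the first ~7 years) and long-term causes (literature follow-up over
decades).  Each cause gets a Weibull distribution; the mixture
`F(t) = w·F_short(t) + (1−w)·F_long(t)` is normalized by construction and
fitted to observed cumulative revision fractions by unweighted least squares
on the CDF scale, using 32 deterministic multi-start points with bounded
local optimization (`scipy.optimize.least_squares`).  Components are
ordered post-fit so the short cause has the smaller median.  Failure times
are sampled by bracketed root-finding on the CDF (no closed-form quantile
exists for the mixture).  On noise-free synthetic curves the fit recovers
random true mixtures essentially exactly (weight to ±0.05, components to
≤5% relative error; in practice ~1e-15).

## Effect sizes

No study measures joint-replacement efficacy directly on the DALY
disability weight, so instrument scores are cross-walked.  With scores
mapped to [0, 1] oriented higher-is-better (linear range rescale;
higher-is-worse instruments such as HAQ flipped after rescaling),

    Effect  = (Score_post − Score_pre) / (1 − Score_pre)
    DW_post = DW_pre · (1 − Effect).

These functional forms implement the assumption that the relative
improvement in residual health deficit is instrument-invariant; alternative
algebra (e.g. absolute score differences) would satisfy weaker versions of
the same assumption, so this is the model's single most consequential
interpretive choice and is isolated in `oasim.effects`.

* Knee effects are pooled by unweighted non-parametric bootstrap (5,000
  replicates) over per-study effects; the PSA samples knee (and hip
  revision) effects from beta distributions matched to the published
  mean/SD by method of moments.
* Hip primary effects are sampled through a regression pathway: normal
  coefficient draws predict pre/post scores which enter the cross-walk.
  The published coefficient set is unavailable, so the configuration
  carries a synthetic two-coefficient regression (intercept = pre-surgery
  score 0.35, slope = gain) calibrated by the delta method to reproduce the
  published effect mean and SD per sex; it is tagged as invented.
* Revision effects apply to the failed-implant state, not the original OA
  state.

## Outcome accounting

Disability combines multiplicatively across the two joints and the
comorbid background rate: `DW_total = 1 − (1−bg)(1−dw1)(1−dw2)`, the
standard burden-of-disease combination, which keeps totals in [0, 1].  The
background rate is the person's stratum PYLD-derived annual rate at entry,
held fixed over life.  After death `DW_total = 1`, so a lost life-year is a
full DALY; DALYs averted are the discounted integral of the comparator −
intervention difference taken over the union of both arms' state-change
times up to the later death.  Integrating the *difference* on a common
partition makes the null case (identical arms) cancel exactly in floating
point, and reproduces by hand both the same-lifespan case and the
surgical-death case (−(1 − DW_comparator) per lost year).

Costs per operation follow the unit-cost table: government DRG cost by
site/operation/complication class, other surgery-related costs,
out-of-pocket costs, and (scenario-dependent) time costs comprising
pre-surgical visits plus sex-specific surgery-and-recuperation time values.
The cost offset is operationalised per affected joint-year: the annual OA
expenditure accrues while a joint is in a symptomatic OA state or a
failed-implant state and stops while an implant functions; the offset is
the discounted difference between arms.  Unrelated future health costs are
the stratum's annual expenditure integrated (signed) between the two arms'
death times — positive when surgery extends life, negative for surgical
deaths.  All flows are discounted continuously at 3%/year
(`∫(1+r)^(−t) dt`, analytic per segment).

Reported per-person values follow the field's reporting convention: costs
to two significant figures, DALYs per person to one decimal.

## Probabilistic sensitivity analysis

The uncertainty table splits parameters into first-order (individual-level:
all time-to-event inputs) and second-order (population-level: effect sizes
and unit costs).  The PSA redraws only second-order parameters, 2,000 times
at full scale: surgery costs from Gamma(shape = unit cost, scale = 1) —
this parameterisation is retained deliberately even though the implied
relative SD (1/√cost) is tiny — and out-of-pocket/time unit costs from
Triangular
(±20%); effects as above.

Because event histories do not depend on second-order parameters, the
cohort is simulated once and reduced to sufficient statistics
(disability-state occupancy weights on the union partition, discounted
operation counts by class, offset joint-years, unrelated person-years by
band).  Each iteration re-prices these exactly; agreement with the
per-person route is verified to ~1e-13 in the tests.  ICERs are summarised
as the mean of per-iteration ratios with percentile 2.5/97.5 uncertainty
intervals; the ratio of means is reported alongside, labelled, since
estimator conventions differ across the literature.

Scenarios form the full 2×2×2 grid of cost offset × time costs × unrelated
future costs.  By construction, removing the offset and adding time costs
can only increase incremental cost at matched seeds.

## Synthetic inputs and what the tests show

The epidemiological inputs of the original analysis (life tables,
progression and uptake rates, fitted implant-failure parameters, regression
coefficients, empirical time-to-event curves) are not publicly available.
The fixture module therefore supplies invented stand-ins, each tagged
`fixture-invented` in the parameter provenance map, alongside the verbatim
printed tables (tagged by table of origin):

* mortality: Gompertz-like, `0.0018·e^(0.085·(age−42.5))`/year for males
  (females ×0.65), flat within 5-year bands;
* progression (per year): incidence 0.03, radiological→symptomatic 0.10,
  symptomatic→advanced 0.07 (hip) / 0.08 (knee), advanced→severe 0.20 / 0.22;
* surgical uptake 0.15 (hip) / 0.12 (knee) per severe-symptomatic
  joint-year; surgical death 0.006; complications 0.13 primary / 0.20
  revision;
* implant mixtures resembling registry curves: hip short (1.2, 3.0 y) /
  long (3.0, 24 y), weight 0.25; knee (1.1, 2.5) / (2.8, 20), weight 0.30;
* disability weights 0 / 0 / 0.06 / 0.10 / 0.30 along the grade ladder,
  failed implant 0.35; PYLD-derived background rate rising 0.04→0.30 with
  age; OA expenditure offset AUD 600 per affected joint-year; unrelated
  expenditure 1,500 + 110·(age − 42.5) AUD/person-year;
* cohort: the published sex totals per site (hip 30,347 M / 38,561 F; knee
  42,930 M / 57,727 F), scalable; invented age distribution concentrated at
  60–79; bilateral proportion 0.5; the qualifying joint is joint 0.

Consequently the pipeline's *population* outputs (total DALYs averted,
scenario costs, ICERs) are not expected to reproduce published values —
they depend on the
invented epidemiology — and the test suite asserts mechanics instead:
worked-example arithmetic on the printed tables, parameter recovery,
hand-traced degenerate schedules, exact null invariance, life-table
calibration, copula correlation, bootstrap recovery, outer-loop Monte Carlo
convergence, and scenario orderings.  Passing tests demonstrate that the
machinery is correct, not that the invented inputs match Australian
epidemiology.

## Problem sizes and numerical choices

Analysis scripts and the acceptance script run at 2% cohort scale with 200
PSA iterations (hip 1,378 / knee 2,014 persons), which keeps every run in
seconds while leaving Monte-Carlo error well inside the reported intervals;
the convergence test compares 200 against 2,000 iterations at 5% scale.
Other choices: CDF inversion tolerance 1e-12 (brentq); out-of-support
second-order draws are redrawn up to 1,000 times then clipped; sampled
effects are clipped to [0, 1]; the regression pathway rejects and redraws
coefficient vectors whose predicted scores leave the unit interval (bounded
at 100 retries); zero hazards yield +inf event times (event never occurs).

## Known limitations

* The score-to-effect cross-walk algebra is an adopted interpretation of
  the instrument-invariance assumption, not an empirically identified form.
* One site per person; no hip+knee co-affected persons; no waiting lists;
  no resurfacing/uni-compartmental procedures.
* The background disability rate is frozen at the entry stratum rather than
  ageing with the person.
* The grade ladder is a simplification of the symptomatic/asymptomatic
  branching in the published taxonomy.
* First-order noise is common across PSA iterations (by design, per the
  first/second-order split); uncertainty intervals therefore reflect
  parameter uncertainty only.
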