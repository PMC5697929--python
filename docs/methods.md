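# Methods

`partmig` re-implements, as a tested pipeline on synthetic data, a seasonal
survival analysis of a partially migratory songbird population: some birds
migrate away for the winter while others stay resident year-round, and the
question is whether migrants buy a winter-survival advantage that residents
must offset through higher breeding success.

## The statistical model

The data object is an encounter history: for each marked bird, a 0/1 vector
over sampling occasions, where each occasion is an operationally defined
season (summer starting 2 March, winter starting 3 November; Y study years
give 2Y − 1 alternating occasions, e.g. 15 for 2009–2016).

Survival and detection are estimated jointly with a multi-event
(hidden-Markov) Cormack–Jolly–Seber model. The shipped state space is
{alive, dead}:

* an individual enters at its first capture (the likelihood conditions on
  that detection);
* alive at occasion *t*, it survives the interval leaving *t* with
  probability Φ(t); dead is absorbing;
* alive at an occasion, it is detected with probability P(t); dead
  individuals are never detected.

The likelihood is evaluated by the forward algorithm over the hidden
states; an independent closed-form CJS implementation (detection products
plus the recursive χ "never seen again" term) serves as an oracle and must
agree to 1e−10. A generic-state forward pass (`forward_loglik`) accepts
arbitrary finite state/emission structures — e.g. a three-state
{alive-present, alive-absent, dead} configuration — but only the two-state
model is exercised by the tests.

**Interval season labelling.** The survival interval leaving occasion *t*
carries occasion *t*'s season type: "summer survival" links a summer
occasion to the following winter occasion. The source study does not print
its convention; this one makes winter/summer effects estimable as interval
effects and is fixed throughout.

**Linear predictors.** Both rates are logit-linear with additive two-level
factors (season type, migratory strategy, sex, age at capture; optionally a
fully time-varying occasion factor), treatment-coded against the references
summer / resident / female / adult. Age is age *at first capture* and never
transitions. Interactions are deliberately out of scope: the candidate
model set contains none.

**Fitting.** Quasi-Newton (L-BFGS-B) maximisation with finite-difference
(3-point) gradients, five seeded multistarts (zero vector plus uniform
draws in [−2, 2]), ties broken by deviance then coefficient norm.
Coefficients are boxed to |β| ≤ 15 on the logit scale: a rate within 3e−7
of 0/1 is numerically at the boundary, where the likelihood is flat and an
unbounded line search stalls. Any fitted rate within 1e−4 of 0/1 raises a
boundary flag. The coefficient covariance is the inverse observed Hessian
(central finite differences, relative step 1e−4); 95% CIs are Wald on the
logit scale back-transformed through the inverse link, hence asymmetric —
matching the asymmetric published intervals. Identical (history, covariate
class) rows are collapsed into weighted pseudo-individuals before
optimisation; this is exact and purely a speed-up.

**Deviance** is −2 × the maximised conditional-on-first-capture
log-likelihood with no saturated-model offset; only deviance *differences*
are ever interpreted.

## Model selection

QAICc = deviance/ĉ + 2K + 2K(K+1)/(n_eff − K − 1), with Akaike weights
w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2). Defaults: ĉ = 1 (the source never
states the ĉ behind its "QAICc" header) and n_eff = number of included
individuals (the effective-sample-size convention is likewise unstated;
both are recorded in the output table header and configurable). The default
candidate set is the published 16-row comparison with one duplicated row
represented once (15 unique formulas); two printed parameter counts in that
table are arithmetically impossible for additive two-level models and the
correct counts are used.

## The synthetic world

`SimulationConfig` defaults *are* the study's stated conditions: 192
residents + 70 migrants, 8 years (15 occasions), summer survival 0.89,
winter survival 0.57 (residents) / 0.73 (migrants), per-occasion detection
0.74 / 0.19, entry at summer occasions (birds were tagged in spring/summer),
one guaranteed detection at entry, strategy fixed for life. Sex and
age-at-capture compositions use the published cohort fractions.

**Migrant summer survival** defaults to the logit-additive value
expit(logit 0.89 + [logit 0.73 − logit 0.57]) ≈ 0.943, making the generator
the exact data-generating twin of the additive season + strategy model the
analysis fits. The stated rates alone (equal summer survival, strategy
effect only in winter) are *not* logit-additive, and fitting the additive
model to such data leaves an irreducible ≈0.04 bias on migrant winter
survival. The additive world is also what the study's own second-ranked
model implies (migrant summer survival reported at 0.94–0.95).
`phi_summer_migrant` overrides the default for an interaction world.

**Phenology.** Departures are truncated-normal around 16 October (SD 12 d)
inside the printed 19 September – 12 November window; arrivals around
14 March (SD 8 d) inside 17 February – 25 March. The SDs are not printed
anywhere and were chosen so that ±2 SD roughly spans the printed ranges.
Season boundaries use the printed means; the real yearly variation (SDs
14.5 and 7.4 d) is not simulated, so the calendar is deterministic.

**Dated records.** `simulate_detection_records` emits the raw stream the
classifier consumes: daily presence for residents and
presence-until-departure for migrants *within occasions where the
encounter matrix is 1*, nocturnal-departure events for migrants (the
automated recording units detect departures independently of the
mark–recapture protocol), and mid-winter (1 Dec – 1 Feb) aerial fixes for
migrants detected in winter occasions. Restricting records to detected
occasions makes the records → matrix round-trip exact for every seed, at a
modelling price: a true resident is classifiable in a year only when
detected in both that year's summer and winter occasions, so a realistic
fraction of residents ends up "undetermined" — mirroring the large
undetermined class (158 of 469) in the real cohort. Optional planted
individuals (winter departers, strategy switchers, pre-cutoff tag
failures, unsexed juveniles) exercise the exclusion filters; their records
are scripted and their matrix rows derived from the scripts, so round-trip
identity is preserved.

The generator does **not** emulate: within-season mortality timing (death
happens between occasions), per-visit detection effort, tag failure as a
process (tag-failure birds are planted, not emergent), natal or breeding
dispersal, strategy switching as a behavioural process, or density
dependence. A green recovery test therefore establishes that the estimator
recovers the generating rates in this idealised world, not that the field
estimates are unbiased.

## Data preparation

Occasion windows are half-open [start, next start), so every date maps to
exactly one occasion; a detection on a boundary date belongs to the
occasion starting that day. Records outside the calendar are dropped with
a warning and counted.

Strategy classification per bird-year: **migrant** if a nocturnal departure
falls in September–November and no detection follows within 14 days
(`min_absence_days`, configurable — the operational absence threshold is
not stated in the source); **resident** if detections cover 1 September –
30 November with no gap above the threshold (the printed residency cutoff
"31 November" does not exist; 30 November is used); **winter departer** if
the nocturnal departure falls after 30 November and before 2 March;
**undetermined** otherwise. Year labels combine to a final strategy:
migrant + resident in different years ⇒ switcher; any winter departure
dominates the rest; all-undetermined ⇒ undetermined. Classification is
idempotent and insensitive to record order.

Exclusion filters remove, in order: undetermined birds, winter departers,
switchers, and unsexed juveniles; the tallies partition the input exactly.

**A caveat the pipeline inherits from the design of the study:** residents
are included only if classified, i.e. only if present through 30 November
of some year, which conditions the included cohort on surviving its first
summer interval. Fitted summer survival on the classification-filtered
cohort is therefore biased towards 1 (it sits at the boundary in pipeline
runs). Model *ranking* is robust to this (every candidate model is fit to
the same conditioned data, and the season × strategy structure survives),
but the pipeline's break-even stage consequently defaults to the
configured survival rates rather than the conditioned fitted ones;
`ess_from_fit=True` opts into the fitted rates.

## The break-even calculation

With winter survival s1 and summer survival s2, the expected lifetime
number of breeding seasons is

    E(s1, s2) = s1 + s1·s2 / (1 − s1·s2),

the closed form of the series in which the first breeding requires
surviving one winter and each later breeding one further summer + winter.
E(0.73, 0.89) = 2.58 and E(0.57, 0.89) = 1.60 (2 dp), so residents need
(2.58/1.60 − 1) = 61.25% higher breeding success for fitness equality.
Note the published 61.25% arises from the 2-dp-rounded expectancies; the
full-precision ratio gives 61.58%. `breakeven_excess(..., rounding=2)` is
the replication mode and both are exposed. The brute-force series oracle in
the tests uses 5,000 terms so the tail is below 1e−10 over the whole
s1·s2 ≤ 0.99 range.

## Numerical conventions

* forward ≡ oracle tolerance: 1e−10 absolute on the log-likelihood;
* optimiser: gtol 1e−8, ftol 1e−13, max 1000 iterations per start;
* nested-model deviance monotonicity is asserted to 1e−4;
* boundary flag threshold: 1e−4 on the rate scale;
* all simulation randomness flows from one integer seed through three
  independent named streams (population draws, record dates, planted
  individuals), so the encounter matrix is identical whether or not dated
  records are materialised.

## Known limitations

* Apparent survival confounds death with permanent emigration; nothing in
  the package separates them.
* No goodness-of-fit machinery (ĉ estimation, U-CARE-style tests); ĉ is a
  user input.
* Only additive two-level factors (plus full time dependence); no
  interactions, no individual random effects, no multistate movement.
* The three-state configuration of the generic forward pass is an example,
  not a tested claim.
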