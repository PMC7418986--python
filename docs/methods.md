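# Methods

`ursaconflict` implements an inference chain that links a hunted wildlife
population to yearly human–wildlife complaint counts. The chain has five
analytic stages — harvest-record cleaning, cohort reconstruction of the
population, a natural-food index, complaint imputation, and an AICc
competition of linear complaint models — plus an individual-based simulator
that generates every observable stream with known truth, so each stage can
be validated against exact tallies rather than against itself.

## The population model behind the observables

The simulator tracks individual bears. Each calendar year proceeds
births → natural deaths → pre-hunt census → harvest; "pre-hunt population"
always means the census between natural mortality and the hunting season,
which is what cohort reconstruction estimates. Births are Poisson with a
per-capita rate per adult (age ≥ 3) female; natural mortality and harvest
are independent Bernoulli events with age-class (and, for harvest,
sex-specific) probabilities. Nothing survives past age 30. Harvest
probabilities are scaled by a year-indexed effort multiplier and inflated in
poor-food years (bait is more attractive when wild food fails). Density
dependence is deliberately absent: the trajectory shape is controlled by the
effort schedule, which is the quantity a management agency actually moves.

Default conditions (chosen once, as the study conditions):

| parameter | default | rationale |
|---|---|---|
| span | 1981–2019 | four decades, policy change mid-series |
| initial abundance | 10,000 | population doubles to ~20,000 then halves |
| birth rate | 0.85 cubs / adult female / yr | annualised litter production; biennial litters of ~2.5 cubs, averaged (reproductive scheduling does not matter for reconstruction or regression) |
| natural mortality | 0.25, 0.15, 0.10, 0.08+ by age | cub-heavy schedule typical of the species |
| base harvest rate | F 0.04–0.14, M 0.05–0.18 by age | male-biased vulnerability |
| effort schedule | 0.32 / 1.00 / 1.55 / 0.80 at years 0 / 11 / 16 / 21 | produces growth to ~2× then decline to ~½ of peak, then stability |
| food rating | Normal(64, 8), failures Normal(46, 2.5) with p = 0.18 | mean near 63 with episodic failures every ~5–6 years |
| sex misreport rate | 0.11 | share of harvested females recorded as males |
| complaint model | 1400 + 0.2·POP − 30·FOOD − 500·POLICY + N(0, 150²) | yields ~1,500 complaints at 10,000 bears rising past 4,000 at the peak in a poor-food year |
| phone fraction | 0.60 at 1984, +0.0125/yr | ~0.6 in the mid-1980s rising to ~0.77 by the late 1990s |

The complaint model is a stand-in: no generative model for complaints is
implied by the analysis being emulated, which only *fits* a linear model.
Complaint noise is Gaussian on the count scale (the analysis is ordinary
linear regression, not a count model), rounded to integers and clipped at
zero with a warning. Nuisance kills are rendered as a Poisson count around
4% of complaints and are **not** removed from the simulated population; they
are ~1% of abundance, and tying them to individual fates would break the
harvest-only oracle contract used to validate reconstruction exactly.

The phone/on-site split of complaint totals is binomial by default. A
`deterministic` split mode applies the exact trend fraction and produces
fractional counts; it exists so imputation can be validated by an exact
round trip, and is labelled a validation mode for that reason.

## What the simulator does not emulate

Spatial structure, local complaint hotspots, bait-site learning,
translocation, biennial reproduction, observer heterogeneity in food scoring
beyond independent binomial noise, and under-recording of complaints by
busy staff. Passing tests therefore demonstrate that the chain recovers
truth under its own stated assumptions — not that those assumptions hold
for any particular agency's records.

## Harvest-record cleaning

Hunters misreport the sex of a fraction r (default 0.11) of harvested
females, essentially never the reverse. The corrected female total is
F′ = F/(1 − r); the excess F′ − F is moved from the male to the female
column, allocated across age classes proportionally to that year's male age
distribution (the correction is a totals-level rescaling, and the data say
nothing about which ages were misrecorded, so the male age mix is the only
available allocation rule). Yearly grand totals are conserved exactly and
corrected counts may be fractional; all downstream arithmetic is
real-valued. The correction commutes with age pooling, which is tested on
fuzzed tables.

PREVKILL(y) = harvest(y−1) + nuisance kills(y−1); the first covered year has
no value and never enters a regression. Interior gaps are errors, never
filled.

## Cohort reconstruction

For each sex and birth cohort, pre-hunt abundance at age a in year
cohort + a is the cohort's cumulative observed harvest at ages ≥ a — the
virtual-population identity: every reconstructed animal eventually appears
in the harvest record. Exact ages are kept internally (needed for the
6+-year-old female tally); the 3+ plus-group is a reporting view.

Two consequences shape the contract:

- **Terminal bias.** Cohorts still alive at the end of the data are only
  partially summed, so late-series estimates are biased low. The final
  2 data years are flagged unreliable and dropped from covariate output
  (with ages pooled at 3+, estimates run to 2 years before the last
  harvest: data through 2019 support covariates through 2017). The
  6+-female covariate POPF6 needs older cohorts observed longer and is
  withheld for 3 further years (through 2014 on the same data). Estimates
  are dropped, not down-weighted.
- **Scale, not shape.** Animals dying of non-hunting causes are invisible,
  so every cell is divided by (1 − f) with f = 0.35 the non-hunting share
  of total mortality. The scale-up is identical in every year and leaves
  year-to-year ratios unchanged; the acceptance surface over reliable years
  is trend fidelity (Pearson r with truth), not absolute abundance.

Covariates emitted per reliable year: POP (total), POPF6 (females ≥ 6),
POPLEVEL = 1(POP > 15,000).

## Food index

Per species and respondent, the two 0–4 scores multiply (range 0–16); the
respondent mean per species is summed over the 14 species (range 0–224).
All species are equally weighted, and the known non-linearity of the 0–4
production scale is not rescaled — both are properties of the index being
emulated, kept deliberately. Category labels use empirical terciles of the
observed ratings by default (the categorization rule behind the original
poor/normal/abundant labels is not documented); fixed cutpoints can be
supplied, and ties — including an all-equal degenerate distribution —
resolve to "normal". A missing species-year is an error, never imputed.

## Complaint imputation

Anchor years with both counts recorded (1984–85 and 1996–98 by default)
supply observed phone fractions; an ordinary least-squares line on calendar
year — on the fraction scale, matching the straight-line treatment being
emulated; a logit variant is available but not default — predicts p̂(y) for
each masked year, and total(y) = onsite(y)/(1 − p̂(y)). All anchor years
enter individually rather than as period means. A predicted fraction
outside (0, 1) is an extrapolation error and raises. On noise-free data
with a deterministic split the round trip is exact to floating point.

## Model competition

Candidates are OLS regressions of COMPLAINTS on predictor subsets; every
candidate keeps a population measure (POP in set 1; POP, POPF6 or both in
set 2), with FOOD, POLICY, PREVKILL optional and POPLEVEL (set 1 only)
optional — 16 models in set 1, 24 in set 2, overridable. Scoring uses
explicit formulas:

- log L = −(n/2)(log 2πσ̂² + 1), σ̂² = RSS/n (full Gaussian ML form; the
  2π constant cancels in ΔAICc and weights, which is why Δ, not absolute
  AICc, is the meaningful scale);
- k = slopes + intercept + residual variance (4 slopes ⇒ k = 6);
- AICc = −2 log L + 2k + 2k(k+1)/(n − k − 1);
- w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2), cumulative weights in rank order,
  ΔAICc ≤ 4 as the default reporting filter;
- adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1);
- VIF_j = 1/(1 − R²_j) from regressing predictor j on the others with
  intercept (perfect collinearity reports ∞, not an exception);
- residual ACF r_h = Σ(e_t − ē)(e_{t+h} − ē)/Σ(e_t − ē)², bounds
  ±1.96/√n.

OLS solutions come from statsmodels; the information-theoretic and
diagnostic layers above are computed from the formulas and cross-checked
against statsmodels' independent implementations in tests. POLICY is coded
1 from the policy year (1998) inclusive even though the real transition
phased in over three years. No multiple-testing correction is applied;
ranking is information-theoretic only.

## Validation design and problem sizes

- **Exact oracle.** Under harvest-only mortality with every cohort extinct
  by the last data year (arranged by making harvest certain at age 30 and
  taking every survivor in the final season), cohort summation must equal
  an independent tally over individual fate records cell-by-cell. Run at
  5,000 starting individuals × 40 years.
- **Trend recovery.** 100 replicates at 4,000 starting individuals over 30
  years with natural mortality 0.10–0.20 and harvest rates 0.15–0.25;
  median Pearson r between adjusted POP and true pre-hunt totals ≥ 0.95.
  The birth rate (1.2) keeps the heavily hunted population viable for the
  full span.
- **Model recovery.** Complaints generated under the threshold-augmented
  model (POP + FOOD + POLICY + POPLEVEL; POPLEVEL step 400, noise sd 150,
  n = 36 on a fixed default-condition design); the generating model must
  rank first in ≥ 70% of 200 replicates, and 95% CIs must cover the
  generating coefficients at the nominal rate. The step size and noise sd
  were fixed by a design-stage power analysis and are part of the study
  conditions.
- Property tests (hypothesis, seeded) cover conservation, commutation,
  monotonicity and permutation invariances.

These sizes keep the full suite around 1–2 minutes and the acceptance
script under a minute on one CPU.

## Known limitations

- Reconstruction reports no uncertainty; it is a point estimator whose
  late-series cells are biased low by construction.
- The 35% non-hunting-mortality share is treated as constant over four
  decades; any real trend in it would bend the reconstructed trajectory.
- The empirical-tercile food categories depend on the observed window and
  are not comparable across datasets.
- Imputed complaint totals inherit any error in the linearity of the phone
  trend, and the imputation does not propagate its regression uncertainty
  into the model competition.
- With POP and POPF6 in the same model the design is near-collinear (VIF
  far above 10); the competition machinery reports this rather than
  preventing it.
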