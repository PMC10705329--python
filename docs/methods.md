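# Methods

## Projection model

The population model is a female-only, three-stage Leslie matrix with
stages fawn (0–1 yr), yearling (1–2 yr) and adult (≥2 yr). Surviving
fawns and yearlings advance one stage per annual time step; surviving
adults remain adults. The matrix has exactly five structural entries —
two fecundities on the top row and three survivals on the subdiagonal and
the adult diagonal — and the model assumes density independence,
geographic closure, constant fecundity, and no fawn reproduction.

Fecundity is F_i = (B_i × S_i)/2: of B_i fawns born per female of stage
i, half are female (1:1 birth sex ratio) and the mother must survive the
year to contribute them. Birth rates default to 1.09 fawns/yearling and
1.43 fawns/adult. `StageVitalRates` derives fecundities from the point
survivals but accepts explicit overrides, which the harvest scenarios use.

Eigen-analysis uses the dense `numpy.linalg.eig` on the 3×3 matrix (and
its transpose for the left eigenvector); the dominant pair is validated to
be real and positive, w is normalized to proportions and v to a fawn
reproductive value of 1. Sensitivities use the eigenvector identity
s_ij = v_i w_j / ⟨v, w⟩ and elasticities e_ij = (a_ij/λ) s_ij, reported
for the five structural entries only: because the scenarios hold
fecundities constant, the survival that appears inside a fecundity product
is deliberately not chained through. Tests verify the eigen residuals to
1e-9, agreement of the sensitivity formula with central finite differences
(step 1e-6) to 1e-5, the unit elasticity sum, and stage-wise
inflow/outflow conservation of elasticities on random valid matrices.

Integer stable-stage abundances use largest-remainder rounding of
w × total, so components always sum exactly to the total. For the
observed rates and a total of 500 this allocates (192, 32, 276); plain
nearest rounding gives the same split, the remainder adjustment only
guards pathological totals.

## Stochastic projections

Each scenario fixes the fecundities and assigns each stage survival a
draw interval — the 95% CI of its estimate. Every projection year of
every replicate redraws the three survivals independently from
Uniform(lower, upper) (all values in the CI equally likely, standing in
for environmental variation such as acorn-crop fluctuation), reassembles
the matrix and multiplies the abundance vector. Abundances are
continuous: only parameter stochasticity is modelled, no
Poisson/binomial demographic noise. Defaults are 10 years, 1000
replicates, and the (192, 32, 276) stable-stage start.

The per-replicate growth rate is the realized geometric mean
(N_T/N_0)^(1/T) of total abundance. The mean of the drawn matrices'
dominant eigenvalues is available as `lambda_method="eigen_mean"`; with
degenerate intervals both collapse exactly to the deterministic λ (from a
stable-stage start the realized rate equals λ to machine precision,
which the tests assert). Summaries report the replicate mean, the
25th–75th percentile range of per-replicate λ (matching the
per-iteration framing of the published growth-rate histogram), and the
fraction of replicates with λ > 1. Sensitivities and elasticities are
computed for every drawn annual matrix (10 × 1000 per scenario) and
arithmetically averaged; per-replicate-then-grand averaging would be
identical and is not separately exposed.

Seeding: one master seed feeds a `numpy.random.SeedSequence`, which
spawns an independent PCG64 substream per replicate, so results are
bit-reproducible and independent of replicate execution order. The
pipeline derives per-scenario child seeds (< 2³¹) from the master seed
the same way.

### Scenario catalog

The five built-in scenarios encode the study's parameter table: (1)
observed rates (S_f 0.157 [0.091–0.273], S_y 0.952 [0.866–1.000], S_a
0.835 [0.748–0.931], F_y 0.519, F_a 0.597); (2) non-hunting adult
survival 0.857 [0.772–0.950] with F_a recomputed to 0.613; (3) the
non-hunting yearling/adult bounds and both fecundities multiplied by
0.95 for a 5% antlerless harvest; (4) and (5) moderate (0.270
[0.185–0.398]) and high (0.430 [0.290–0.570]) fawn survival. The
yearling survival is a literature substitution — the collared yearling
sample had no deaths, so its own estimate (1.0, degenerate CI) is
uninformative — and the upper bound 1.000 is inclusive in the draws.

Scenario 3 follows its source table literally and carries a known
internal inconsistency: the survival baselines are the non-hunting
estimates, but the fecundities discounted by 0.95 are the
harvest-inclusive scenario-1 values (0.597 rather than 0.613 for
adults). `builtin_scenarios(consistent_baseline=True)` instead discounts
the non-hunting fecundities.

### Break-even fawn survival

With all other rates at their point estimates, λ(S_f) = 1 is solved by
Brent bisection on [0, 1] (tolerance 1e-6); the characteristic polynomial
at λ = 1 gives the closed form (1 − S_a)/(F_y + F_a S_y − F_y S_a). At
the observed parameters both routes give ≈ 0.2523. The source analysis
reports ≥ 0.256 for the same quantity without stating its method (possibly
a coarse increment search or a stochastic-mean criterion); the solver
returns the analytic value and the discrepancy (< 0.005) is surfaced as a
documented check, not forced to match. Similarly, the scenario-4 mean
growth rate is printed as 1.018 in the source's results and 1.019 in its
abstract; this implementation targets the results-section value.

## Survival estimation

`km_curve` is a hand-implemented product-limit estimator on a shared
calendar-time axis with staggered entry: the risk set at a death time t
is {entry ≤ t and exit ≥ t}. Survival steps only at death times;
simultaneous deaths use the 1 − d/n multiple-decrement factor; censoring
at a death time is processed after the deaths, so those animals remain
in that risk set. Greenwood's variance accumulates per step, and the 95%
CI applies the complementary log–log (exponential Greenwood) transform,
degenerating gracefully at S = 0 or S = 1 (a cohort with no deaths
returns a point of 1.0). An empty risk set at a death time raises an
estimation error rather than being skipped. The implementation is
cross-checked in the tests against lifelines'
`KaplanMeierFitter(entry=...)`, which reproduces the point estimate and
CI to 1e-10 — the library serves as the independent oracle, never the
implementation.

Multi-season designs are pooled with `pool_study_years`, which re-bases
each animal's times to the origin of the study year it entered, matching
the convention of pooling small annual samples into one curve. Harvest
handling defaults to `remove_animal` (harvested animals deleted, the
sample size drops) because that is the convention the non-hunting
survival estimate follows; `censor_at_death` provides the standard
alternative. CI coverage is verified by simulation: over 200 synthetic
cohorts of 200 animals the 95% log–log interval covers the true rate at
a frequency within [0.90, 0.99].

## Synthetic data generator

The generator emulates the monitoring design the estimators assume: three
annual capture seasons with entries uniform on a January–April window
(days 0–120 of each study year), follow-up to the end of a 3-year study,
exponential death times with the constant hazard −ln(S)/365 calibrated so
365-day survival equals the requested rate (no within-year hazard shape is
assumed anywhere, so constant hazard is the minimal choice), and death
labels drawn harvest with a fixed probability. Fawn cohorts draw litter
sizes from the two-point mixture on adjacent integers matching the
requested mean (mean 1.43 → P(twins) = 0.43) and use an 84-day horizon.
Default parameters mirror the field study's scale: 45 adults + 14
yearlings collared over three years, 71 fawns, adult survival 0.835, fawn
survival 0.157, 2 of 11 adult deaths hunter-related.

What the generator does *not* emulate: within-year hazard seasonality
(hunting seasons, fawning peaks), temporal autocorrelation between study
years, heterogeneity among individuals, cause-specific competing risks
beyond the natural/harvest label, or spatial structure. Parameter-recovery
tests on this generator therefore validate the estimator arithmetic and
the pipeline plumbing, not robustness to those real-data features.

## Numerical conventions and problem sizes

Scenario runs use the published design (1000 replicates × 10 years)
everywhere the published summaries are compared; property and recovery
tests use smaller designs (50–400 replicates, cohorts of 200–5000
animals) chosen so binomial/Monte-Carlo error stays well inside the
asserted tolerances. Reports round to presentation precision (λ to 3
decimals, percentages to whole points) while JSON artifacts keep full
precision. All randomness flows from explicit integer seeds; derived
seeds stay below 2³¹.

## Known limitations

- Density independence and constant fecundity mean projections are only
  meaningful over horizons where those assumptions hold; projected
  abundances are not a calibrated metric and only growth rates are
  summarized.
- The uniform-on-CI draw treats estimation uncertainty as environmental
  variation; it is the source analysis' convention, not a calibrated
  stochastic vital-rate model.
- The male segment, age structure within the adult stage, senescence and
  demographic stochasticity are out of scope.
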